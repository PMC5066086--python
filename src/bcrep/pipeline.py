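"""End-to-end pipeline orchestration and tabular report generation.

Runs annotate -> filter -> SHM -> selection -> clonality -> class-switch
analysis and writes per-donor and per-age-group TSV reports plus Newick
lineage trees and a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .annotate import Annotator, DEFAULT_TRIM
from .clonality import (
    build_lineage_tree,
    clonality_summary,
    clone_frame,
    mutation_matrix,
    partition_clones,
)
from .csr import (
    cross_class_overlap,
    cross_subclass_overlap,
    overlap_frame,
    repertoire_summary,
    subclass_distribution,
)
from .filtering import (
    DEFAULT_MIN_DUPLICATE,
    DEFAULT_MIN_UNIQUE,
    apply_quality_filters,
    filter_donors,
    filter_report_frame,
)
from .germline import CDR_REGIONS, FR_REGIONS, default_germline_db
from .io import read_airr, read_donor_metadata, read_fasta
from .selection import (
    DEFAULT_ALPHA,
    analyze_selection,
    expected_replacement_fraction,
    fraction_selected,
    selection_strength,
)
from .shm import (
    mutation_scan,
    profile_frame,
    shm_profile,
    sunburst_export,
    transition_table_percent,
)
from .types import DonorMetadata, Rearrangement

logger = logging.getLogger("bcrep")


@dataclass
class PipelineConfig:
    """All pipeline thresholds plus input/output paths."""

    input_path: str = ""
    mode: str = "fasta"  # "fasta" | "airr"
    donor_metadata_path: Optional[str] = None
    output_dir: str = "bcrep_out"
    trim_left: int = DEFAULT_TRIM
    trim_right: int = DEFAULT_TRIM
    min_duplicate: int = DEFAULT_MIN_DUPLICATE
    min_unique: int = DEFAULT_MIN_UNIQUE
    clone_max_distance: int = 3
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    min_tree_members: int = 3  # smallest clone for which a Newick tree is written
    max_trees: int = 50

    def validate(self) -> None:
        if self.mode not in ("fasta", "airr"):
            raise ValueError(f"mode must be fasta or airr, got {self.mode!r}")
        for name in ("trim_left", "trim_right"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("min_duplicate", "min_unique", "clone_max_distance"):
            if getattr(self, name) < 1 and name != "clone_max_distance":
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def load_rearrangements(config: PipelineConfig) -> list[Rearrangement]:
    """Load annotated rearrangements per the configured input mode."""
    if config.mode == "airr":
        return read_airr(config.input_path)
    reads = read_fasta(config.input_path)
    annotator = Annotator()
    records, dropped = annotator.annotate_reads(
        reads, trim=(config.trim_left, config.trim_right)
    )
    logger.info("annotated %d reads (%d dropped)", len(records), dropped)
    return records


def analyze(
    transcripts: list[Rearrangement],
    donors: Optional[list[DonorMetadata]] = None,
    config: Optional[PipelineConfig] = None,
) -> dict[str, object]:
    """Run all analysis stages on filtered unique transcripts.

    Returns a dict of DataFrames / objects keyed by report name.
    """
    config = config or PipelineConfig()
    db = default_germline_db()
    rng = np.random.default_rng(config.seed)
    donor_group = {d.donor_id: d.age_group for d in donors} if donors else {}

    strata: dict[tuple[str, str], list[Rearrangement]] = {}
    for r in transcripts:
        strata.setdefault((r.donor_id, r.isotype_class or "NA"), []).append(r)

    # SHM profiles
    profiles = [
        shm_profile(donor, cls, members, db)
        for (donor, cls), members in sorted(strata.items())
    ]
    shm_table = profile_frame(profiles)
    if donor_group and not shm_table.empty:
        shm_table.insert(1, "age_group", shm_table["donor_id"].map(donor_group))

    # transition tables per class (rows germline base, columns observed base)
    transition_rows = []
    sunburst: dict[str, dict] = {}
    for cls in ("IGG", "IGA"):
        table = None
        for p in profiles:
            if p.isotype_class == cls:
                table = p.transition_table if table is None else table + p.transition_table
        if table is not None:
            for germ_base, row in table.iterrows():
                transition_rows.append(
                    {"isotype_class": cls, "germline_base": germ_base, **row.to_dict()}
                )
            sunburst[cls] = sunburst_export(table)
    transition_table = pd.DataFrame(transition_rows)

    # selection
    selection_rows, strength_rows, fig5a_rows = [], [], []
    p_fraction_cache: dict[tuple[str, str], float] = {}
    for (donor, cls), members in sorted(strata.items()):
        results = analyze_selection(members, db, alpha=config.alpha)
        if not results:
            continue
        per_transcript = []
        for r in members:
            if r.v_call and r.v_call[0] in db and not r.has_indel:
                muts, _ = mutation_scan(r, db[r.v_call[0]])
                per_transcript.append(muts)
        # expected replacement fractions use the stratum's modal V gene
        v_names = pd.Series(
            [r.v_call[0] for r in members if r.v_call and r.v_call[0] in db]
        )
        modal_v = v_names.mode().iloc[0]
        summaries = {}
        for region, regs in (("CDR", CDR_REGIONS), ("FR", FR_REGIONS)):
            key = (modal_v, region)
            if key not in p_fraction_cache:
                p_fraction_cache[key] = expected_replacement_fraction(db[modal_v], regs)
            summaries[region] = selection_strength(
                per_transcript, region, p_fraction_cache[key],
                donor_id=donor, rng=rng,
            )
        selection_rows.append(
            {
                "donor_id": donor,
                "isotype_class": cls,
                "n_transcripts": len(results),
                "pct_selected": fraction_selected(results, alpha=config.alpha),
                "strength_cdr": summaries["CDR"].strength,
                "strength_cdr_ci_low": summaries["CDR"].ci_low,
                "strength_cdr_ci_high": summaries["CDR"].ci_high,
                "strength_fr": summaries["FR"].strength,
                "strength_fr_ci_low": summaries["FR"].ci_low,
                "strength_fr_ci_high": summaries["FR"].ci_high,
            }
        )
        point_multiplicity: dict[tuple[int, int], int] = {}
        for res in results:
            point_multiplicity[(res.m_v, res.r_cdr)] = (
                point_multiplicity.get((res.m_v, res.r_cdr), 0) + 1
            )
        for res in results:
            fig5a_rows.append(
                {
                    "donor_id": donor,
                    "isotype_class": cls,
                    "read_id": res.read_id,
                    "m_v": res.m_v,
                    "r_cdr": res.r_cdr,
                    "r_cdr_over_m_v": res.r_cdr / res.m_v if res.m_v else 0.0,
                    "p_value": res.p_value,
                    "selected": res.selected,
                    "multiplicity": point_multiplicity[(res.m_v, res.r_cdr)],
                }
            )
    selection_summary = pd.DataFrame(selection_rows)
    selection_transcripts = pd.DataFrame(fig5a_rows)

    # clonality per donor (IGG+IGA merged)
    by_donor: dict[str, list[Rearrangement]] = {}
    for r in transcripts:
        by_donor.setdefault(r.donor_id, []).append(r)
    clone_rows, clonality_rows, trees = [], [], []
    donor_clones: dict[str, list] = {}
    by_read = {r.read_id: r for r in transcripts}
    for donor in sorted(by_donor):
        clones = partition_clones(by_donor[donor], max_distance=config.clone_max_distance)
        donor_clones[donor] = clones
        donor_of = {rid: donor for c in clones for rid in c.read_ids}
        clone_rows.append(clone_frame(clones, donor_of))
        summary = clonality_summary(clones, donor_id=donor)
        clonality_rows.append(
            {
                "donor_id": donor,
                "n_transcripts": summary.n_transcripts,
                "n_clones": summary.n_clones,
                "max_clone_pct": summary.max_clone_pct,
                "pct_unique_clones": summary.pct_unique_clones,
            }
        )
        for clone in clones:
            if clone.n_members >= config.min_tree_members and len(trees) < config.max_trees:
                try:
                    trees.append(build_lineage_tree(clone, by_read, db))
                except ValueError:
                    logger.warning("skipping tree for %s (conflicting V)", clone.clone_id)
    clones_table = pd.concat(clone_rows, ignore_index=True) if clone_rows else pd.DataFrame()
    clonality_table = pd.DataFrame(clonality_rows)

    # class-switch / repertoire statistics
    group_map = donor_group or None
    subclass_by_donor = subclass_distribution(transcripts)
    subclass_by_age = (
        subclass_distribution(transcripts, strata=group_map) if group_map else None
    )
    overlaps = []
    for donor in sorted(by_donor):
        for family in ("IGG", "IGA"):
            overlaps.extend(cross_subclass_overlap(by_donor[donor], family, stratum=donor))
        overlaps.append(cross_class_overlap(by_donor[donor], stratum=donor))
    overlap_table = overlap_frame(overlaps)

    summary_rows = []
    for (donor, cls), members in sorted(strata.items()):
        s = repertoire_summary(members, stratum=f"{donor}:{cls}")
        summary_rows.append(
            {
                "donor_id": donor,
                "isotype_class": cls,
                "n_transcripts": s.n_transcripts,
                "median_cdr3_length_aa": s.median_cdr3_length_aa,
                "median_junction_deletions": s.median_junction_deletions,
                "median_n_nucleotides": s.median_n_nucleotides,
                "pct_ighv4_34": s.v_gene_usage.get("IGHV4-34", 0.0),
                "pct_ighj4": s.j_gene_usage.get("IGHJ4", 0.0),
                "pct_ighj6": s.j_gene_usage.get("IGHJ6", 0.0),
                "pct_cdr3_tyrosine": s.cdr3_aa_composition.get("Y", 0.0),
            }
        )
    repertoire_table = pd.DataFrame(summary_rows)

    # Fig-6C-style mutation matrix of each donor's largest multi-member clone
    matrix_rows = []
    for donor in sorted(by_donor):
        multi = [c for c in donor_clones[donor] if c.n_members >= 2]
        if not multi:
            continue
        top = max(multi, key=lambda c: c.n_members)
        matrix = mutation_matrix(top, by_read, db)
        for rid, row in matrix.iterrows():
            matrix_rows.append(
                {"donor_id": donor, "clone_id": top.clone_id, "read_id": rid,
                 **{str(pos): val for pos, val in row.items()}}
            )
    mutation_matrix_table = pd.DataFrame(
        matrix_rows if matrix_rows else None,
        columns=None if matrix_rows else ["donor_id", "clone_id", "read_id"],
    )

    return {
        "shm_profiles": shm_table,
        "transition_tables": transition_table,
        "transition_sunburst": sunburst,
        "clone_mutation_matrix": mutation_matrix_table,
        "selection_summary": selection_summary,
        "selection_transcripts": selection_transcripts,
        "clones": clones_table,
        "clonality_summary": clonality_table,
        "subclass_distribution": subclass_by_donor,
        "subclass_by_age_group": subclass_by_age,
        "overlap": overlap_table,
        "repertoire_summary": repertoire_table,
        "lineage_trees": trees,
    }


REPORT_TABLES = (
    "filter_report",
    "shm_profiles",
    "transition_tables",
    "clone_mutation_matrix",
    "selection_summary",
    "selection_transcripts",
    "clones",
    "clonality_summary",
    "subclass_distribution",
    "overlap",
    "repertoire_summary",
)


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute the full pipeline and write the report bundle."""
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)

    records = load_rearrangements(config)
    donors = (
        read_donor_metadata(config.donor_metadata_path)
        if config.donor_metadata_path
        else None
    )

    unique, reports = apply_quality_filters(records, min_duplicate=config.min_duplicate)
    kept, included = filter_donors(unique, min_unique=config.min_unique, reports=reports)
    results = analyze(kept, donors=donors, config=config)
    results["filter_report"] = filter_report_frame(reports)
    results["included_strata"] = sorted(included)

    for name in REPORT_TABLES:
        table = results.get(name)
        if isinstance(table, pd.DataFrame):
            table.to_csv(os.path.join(config.output_dir, f"{name}.tsv"), sep="\t", index=False)
    with open(os.path.join(config.output_dir, "transition_sunburst.json"), "w") as fh:
        json.dump(results.get("transition_sunburst", {}), fh, indent=2)
    if results.get("subclass_by_age_group") is not None:
        results["subclass_by_age_group"].to_csv(
            os.path.join(config.output_dir, "subclass_by_age_group.tsv"),
            sep="\t", index=False,
        )
    trees = results.get("lineage_trees") or []
    with open(os.path.join(config.output_dir, "lineage_trees.nwk"), "w") as fh:
        for tree in trees:
            fh.write(tree.to_newick() + "\n")
    edge_rows = []
    for tree in trees:
        for node in tree.nodes():
            for edge in node.children:
                edge_rows.append(
                    {
                        "clone_id": tree.clone_id,
                        "parent": node.node_id,
                        "child": edge.child.node_id,
                        "child_reads": ",".join(edge.child.read_ids),
                        "n_substitutions": edge.length,
                        "gained": ";".join(f"{p}:{a}>{b}" for p, a, b in sorted(edge.gained)),
                    }
                )
    pd.DataFrame(edge_rows).to_csv(
        os.path.join(config.output_dir, "lineage_edges.tsv"), sep="\t", index=False
    )

    manifest = {
        "bcrep_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_input_records": len(records),
        "n_unique_transcripts": len(unique),
        "n_analyzed_transcripts": len(kept),
        "included_strata": ["|".join(k) for k in sorted(included)],
    }
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results
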