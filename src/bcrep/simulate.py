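"""Truth-tagged synthetic antigen-experienced repertoire generator.

The generator emulates the statistical structure the analysis assumes:
V(D)J-recombined IGH transcripts with junction trimming and N insertions,
clonal lineages (a shared trunk of mutations plus per-member private
mutations) accumulated under a two-phase SHM model (a G/C phase for base
excision repair with AID-hotspot bias, and an A/T spreading phase for
mismatch repair with WA/TW bias), region-dependent selection knobs
(replacement enrichment in CDR, replacement rejection in FR, survivorship
against stop codons), age-dependent subclass usage with downstream-only
class switching, duplicate read depth, and substitution-type sequencing
errors that create singleton variants.  Every emitted read carries a
ground-truth record.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .germline import (
    ANALYSIS_NT_SPAN,
    GermlineDatabase,
    LOCUS_ORDER,
    NUCLEOTIDES,
    SEQUENCED_SUBCLASSES,
    TRANSITION_PARTNER,
    age_group_of,
    default_germline_db,
    translate,
)
from .io import RawRead, write_donor_metadata, write_fasta
from .shm import hotspot_mask
from .types import DonorMetadata, Rearrangement

MutKey = tuple[int, str, str]

#: Founder subclass usage per age group (IGG and IGA families), encoding the
#: qualitative age trends: IGG2/IGA2 share grows with age, IGG1 falls, IGG3
#: peaks in the 4-10 group, IGG4 stays rare.
DEFAULT_SUBCLASS_MODEL: dict[str, dict[str, dict[str, float]]] = {
    "CB": {"IGG": {"IGG1": 0.70, "IGG2": 0.12, "IGG3": 0.16, "IGG4": 0.02},
           "IGA": {"IGA1": 0.92, "IGA2": 0.08}},
    "1-3": {"IGG": {"IGG1": 0.68, "IGG2": 0.14, "IGG3": 0.16, "IGG4": 0.02},
            "IGA": {"IGA1": 0.88, "IGA2": 0.12}},
    "4-10": {"IGG": {"IGG1": 0.60, "IGG2": 0.17, "IGG3": 0.20, "IGG4": 0.03},
             "IGA": {"IGA1": 0.84, "IGA2": 0.16}},
    "11-17": {"IGG": {"IGG1": 0.58, "IGG2": 0.24, "IGG3": 0.15, "IGG4": 0.03},
              "IGA": {"IGA1": 0.80, "IGA2": 0.20}},
    "18-39": {"IGG": {"IGG1": 0.52, "IGG2": 0.32, "IGG3": 0.12, "IGG4": 0.04},
              "IGA": {"IGA1": 0.74, "IGA2": 0.26}},
    "40-74": {"IGG": {"IGG1": 0.45, "IGG2": 0.42, "IGG3": 0.09, "IGG4": 0.04},
              "IGA": {"IGA1": 0.65, "IGA2": 0.35}},
}


def default_donors() -> list[DonorMetadata]:
    """The demo cohort: 38 donors, two cord blood, ages spanning 0-74."""
    ages = [0, 0, 1, 1, 2, 2, 3, 3, 4, 5, 6, 7, 8, 9, 10, 11, 13, 15, 17,
            19, 21, 24, 27, 30, 33, 36, 39, 42, 45, 48, 51, 54, 57, 60, 63,
            66, 70, 74]
    donors = []
    for k, age in enumerate(ages, start=1):
        donors.append(
            DonorMetadata(
                donor_id=f"D{k:02d}",
                age_years=float(age),
                is_cord_blood=(k <= 2),
                sex="F" if k % 2 else "M",
            )
        )
    return donors


@dataclass
class SimulationConfig:
    """Generative parameters; defaults are the demo-cohort study conditions."""

    seed: int = 0
    donors: Optional[list[DonorMetadata]] = None  # None -> default_donors()
    n_clones: int = 70  # per donor per isotype class
    clone_size_exponent: float = 2.5  # Zipf exponent of clone sizes
    max_clone_size: int = 12

    #: Expected substitutions per site over codons 27-104.  None derives the
    #: rate from donor age: a linear ramp 0 -> plateau over the first 6
    #: years (cord blood fixed at ``cb_mutation_rate``) with multiplicative
    #: per-donor lognormal jitter.
    mutation_rate: Optional[float] = None
    plateau_mutation_rate: float = 0.07
    plateau_age_years: float = 6.0
    cb_mutation_rate: float = 0.003
    donor_rate_jitter_sd: float = 0.12
    trunk_fraction: float = 0.4  # fraction of a member's mutations shared clone-wide

    hotspot_bias: float = 3.0  # weight of RGYW/WRCY (G/C) and WA/TW (A/T) positions
    transition_prob: float = 0.5  # probability a substitution is a transition
    gc_phase_fraction: float = 0.55  # fraction of mutations forced onto G/C sites
    cdr_r_enrichment: float = 2.0  # acceptance weight of replacement mutations in CDR
    fr_r_rejection: float = 0.35  # rejection probability of replacement mutations in FR
    allow_stop_mutations: bool = False  # False emulates survivorship against stops
    mutation_retry_budget: int = 100

    subclass_model: Optional[dict] = None  # None -> DEFAULT_SUBCLASS_MODEL
    within_clone_switch_prob: float = 0.15
    member_junction_snp_mean: float = 0.0  # per-member junction divergence
    member_junction_snp_cap: int = 1

    sequencing_error_rate: float = 1e-3  # per base per read copy
    duplicate_depth_mean: float = 3.0  # geometric; P(depth=1) = 1/mean
    duplicate_depth_min: int = 1

    v_del_mean: float = 1.5
    v_del_max: int = 4
    j_del_mean: float = 2.0
    d_del_mean: float = 1.5
    min_d_remnant: int = 8
    n_insert_mean: float = 4.0  # Poisson mean per junction side
    enforce_inframe: bool = True
    min_interclone_distance: int = 0  # 0 = off; redraw same-length junctions closer than this

    add_primer_flanks: bool = True
    primer_len: int = 40

    def validate(self) -> None:
        probs = {
            "transition_prob": self.transition_prob,
            "gc_phase_fraction": self.gc_phase_fraction,
            "fr_r_rejection": self.fr_r_rejection,
            "within_clone_switch_prob": self.within_clone_switch_prob,
            "sequencing_error_rate": self.sequencing_error_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.hotspot_bias < 0 or self.cdr_r_enrichment < 0:
            raise ValueError("weights must be >= 0")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 0.2:
            raise ValueError("mutation_rate must be in [0, 0.2]")
        if self.duplicate_depth_mean < 1:
            raise ValueError("duplicate_depth_mean must be >= 1")
        model = self.subclass_model or DEFAULT_SUBCLASS_MODEL
        order = {sc: i for i, sc in enumerate(LOCUS_ORDER)}
        for group, families in model.items():
            for fam, dist in families.items():
                if abs(sum(dist.values()) - 1.0) > 1e-9:
                    raise ValueError(f"subclass model {group}/{fam} must sum to 1")
                for sc in dist:
                    if sc not in order:
                        raise ValueError(f"unknown constant gene {sc}")


@dataclass
class TruthRecord:
    """Ground truth for one emitted read."""

    read_id: str
    donor_id: str
    clone_id: str
    member_id: str
    duplicate_group: str
    subclass: str
    v_call: str
    d_call: str
    j_call: str
    mutations: list[MutKey]
    junction_nt: str
    v_del: int
    d5_del: int
    d3_del: int
    j_del: int
    n1: int
    n2: int
    is_sequencing_error_read: bool
    error_positions: list[int] = field(default_factory=list)

    @property
    def junction_deletions(self) -> int:
        return self.v_del + self.d5_del + self.d3_del + self.j_del

    @property
    def n_nucleotides(self) -> int:
        return self.n1 + self.n2


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=n))


def _bounded_geometric(rng: np.random.Generator, mean: float, cap: int) -> int:
    if mean <= 0 or cap <= 0:
        return 0
    return int(min(rng.geometric(1.0 / (1.0 + mean)) - 1, cap))


def vdj_recombine(
    config: SimulationConfig,
    rng: np.random.Generator,
    db: Optional[GermlineDatabase] = None,
) -> tuple[str, dict]:
    """Draw V, D, J with junction trimming and N insertions.

    Returns the naive (unmutated) V..J nucleotide sequence and a truth dict
    with the chosen genes, trim counts, N lengths and junction span.
    """
    db = db if db is not None else default_germline_db()
    v = db.v_segments[rng.integers(len(db.v_segments))]
    d = db.d_segments[rng.integers(len(db.d_segments))]
    j = db.j_segments[rng.integers(len(db.j_segments))]

    v_del = _bounded_geometric(rng, config.v_del_mean, config.v_del_max)
    d_budget = max(len(d.sequence) - config.min_d_remnant, 0)
    d5 = _bounded_geometric(rng, config.d_del_mean, d_budget)
    d3 = _bounded_geometric(rng, config.d_del_mean, max(d_budget - d5, 0))
    j_del = _bounded_geometric(rng, config.j_del_mean, max(j.anchor_offset - 1, 0))
    n1 = int(rng.poisson(config.n_insert_mean))
    n2 = int(rng.poisson(config.n_insert_mean))
    if config.enforce_inframe:
        # toy segments are frame-aligned: only trims and insertions shift frame
        shift = (v_del + d5 + d3 + j_del - n1 - n2) % 3
        n1 += shift

    v_part = v.sequence[: len(v.sequence) - v_del]
    d_part = d.sequence[d5 : len(d.sequence) - d3]
    j_part = j.sequence[j_del:]
    sequence = v_part + _rand_nt(rng, n1) + d_part + _rand_nt(rng, n2) + j_part

    junction_start = 309  # 0-based index of V codon 104 (Cys)
    anchor_in_read = len(v_part) + n1 + len(d_part) + n2 + (j.anchor_offset - j_del)
    truth = {
        "v_call": v.name, "d_call": d.name, "j_call": j.name,
        "v_del": v_del, "d5_del": d5, "d3_del": d3, "j_del": j_del,
        "n1": n1, "n2": n2,
        "junction_start": junction_start,
        "junction_end": anchor_in_read + 3,
    }
    return sequence, truth


def mutate_shm(
    sequence: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_mutations: Optional[int] = None,
    rate: Optional[float] = None,
    exclude: Optional[set[int]] = None,
) -> tuple[str, list[MutKey]]:
    """Accumulate hotspot-biased point mutations over codons 27-104.

    The mutation count is Poisson(rate x span) unless given explicitly;
    positions are drawn phase-first (G/C vs A/T per ``gc_phase_fraction``)
    with hotspot weighting, target bases per ``transition_prob``, and
    candidates are re-drawn (bounded budget) when rejected by the selection
    knobs or when they would create a stop codon (survivorship).  Positions
    in ``exclude`` (e.g. a clone's trunk) are never re-used.
    """
    lo, hi = ANALYSIS_NT_SPAN
    hi = min(hi, len(sequence))
    span = hi - lo + 1
    if span <= 0:
        return sequence, []
    if n_mutations is None:
        r = rate if rate is not None else (config.mutation_rate or 0.0)
        n_mutations = int(rng.poisson(r * span))

    rgyw_wrcy, wa_tw = hotspot_mask(sequence)
    positions = np.arange(lo, hi + 1)
    bases = np.frombuffer(sequence.encode(), dtype="S1")[lo - 1 : hi].astype("U1")
    is_gc = np.isin(bases, ["G", "C"])
    weights = np.ones(span)
    flagged = rgyw_wrcy[lo - 1 : hi] | wa_tw[lo - 1 : hi]
    weights[flagged] = config.hotspot_bias

    from .germline import region_of_nt  # local import to avoid cycle at module load
    from .shm import classify_rs

    used: set[int] = set(exclude or ())
    used_mask = np.zeros(span, dtype=bool)
    for p in used:
        if lo <= p <= hi:
            used_mask[p - lo] = True
    w_max = max(config.cdr_r_enrichment, 1.0)
    mutations: list[MutKey] = []
    seq_list = list(sequence)

    for _ in range(n_mutations):
        accepted = None
        for _try in range(config.mutation_retry_budget):
            gc_phase = rng.random() < config.gc_phase_fraction
            mask = (is_gc if gc_phase else ~is_gc) & ~used_mask
            cand = np.flatnonzero(mask)
            if cand.size == 0:
                # phase saturated (dense clones): fall back to the other phase
                cand = np.flatnonzero((~is_gc if gc_phase else is_gc) & ~used_mask)
            if cand.size == 0:
                break
            w = weights[cand]
            k = int(cand[rng.choice(cand.size, p=w / w.sum())])
            pos = int(positions[k])
            from_base = sequence[pos - 1]
            if rng.random() < config.transition_prob:
                to_base = TRANSITION_PARTNER[from_base]
            else:
                options = [b for b in NUCLEOTIDES if b != from_base and b != TRANSITION_PARTNER[from_base]]
                to_base = options[int(rng.integers(2))]
            codon_idx = (pos - 1) // 3
            codon = sequence[codon_idx * 3 : codon_idx * 3 + 3]
            pos_in_codon = (pos - 1) % 3 + 1
            mutated_codon = (
                codon[: pos_in_codon - 1] + to_base + codon[pos_in_codon:]
            )
            if not config.allow_stop_mutations and translate(mutated_codon) == "*":
                continue
            rs = classify_rs(codon, pos_in_codon, to_base)
            region = region_of_nt(pos)
            if rs == "R" and region in ("CDR1", "CDR2"):
                accept_w = config.cdr_r_enrichment
            elif rs == "R" and region in ("FR2", "FR3"):
                accept_w = 1.0 - config.fr_r_rejection
            else:
                accept_w = 1.0
            if rng.random() < accept_w / w_max:
                accepted = (pos, from_base, to_base)
                break
        if accepted is None:
            continue
        pos, from_base, to_base = accepted
        used.add(pos)
        used_mask[pos - lo] = True
        mutations.append(accepted)
        seq_list[pos - 1] = to_base
    return "".join(seq_list), sorted(mutations)


def _downstream_choices(subclass: str) -> list[str]:
    order = {sc: i for i, sc in enumerate(LOCUS_ORDER)}
    return [sc for sc in SEQUENCED_SUBCLASSES if order[sc] > order[subclass]]


def assign_isotype(
    n_members: int,
    age_group: str,
    isotype_class: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, list[list[str]]]:
    """Founder subclass plus per-member subclass lists.

    The clone founder's subclass is drawn from the age-group distribution of
    its family; each member additionally re-switches downstream-only with
    ``within_clone_switch_prob``, in which case both the pre- and
    post-switch transcript (identical variable sequence) are emitted,
    modelling switching without additional SHM.
    """
    model = config.subclass_model or DEFAULT_SUBCLASS_MODEL
    dist = model[age_group][isotype_class]
    names = sorted(dist)
    founder = names[int(rng.choice(len(names), p=np.array([dist[n] for n in names])))]
    per_member: list[list[str]] = []
    for _ in range(n_members):
        subs = [founder]
        if rng.random() < config.within_clone_switch_prob:
            downstream = _downstream_choices(founder)
            if downstream:
                subs.append(downstream[int(rng.integers(len(downstream)))])
        per_member.append(subs)
    return founder, per_member


@dataclass
class SimulatedRepertoire:
    config: SimulationConfig
    reads: list[RawRead]
    truth: list[TruthRecord]
    rearrangements: list[Rearrangement]  # truth-annotated, one per read
    donors: list[DonorMetadata]

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "reads.fasta"),
            "airr": os.path.join(outdir, "rearrangements.tsv"),
            "truth": os.path.join(outdir, "truth.tsv"),
            "donors": os.path.join(outdir, "donors.tsv"),
        }
        write_fasta([(r.read_id, r.sequence) for r in self.reads], paths["fasta"])
        from .io import write_airr

        write_airr(self.rearrangements, paths["airr"])
        truth_frame(self.truth).to_csv(paths["truth"], sep="\t", index=False)
        write_donor_metadata(self.donors, paths["donors"])
        return paths


def truth_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": t.read_id,
                "donor_id": t.donor_id,
                "clone_id": t.clone_id,
                "member_id": t.member_id,
                "duplicate_group": t.duplicate_group,
                "subclass": t.subclass,
                "v_call": t.v_call,
                "d_call": t.d_call,
                "j_call": t.j_call,
                "n_mutations": len(t.mutations),
                "mutations": ";".join(f"{p}:{f}>{b}" for p, f, b in t.mutations),
                "junction": t.junction_nt,
                "v_del": t.v_del,
                "d5_del": t.d5_del,
                "d3_del": t.d3_del,
                "j_del": t.j_del,
                "n1": t.n1,
                "n2": t.n2,
                "is_sequencing_error_read": t.is_sequencing_error_read,
                "error_positions": ";".join(map(str, t.error_positions)),
            }
            for t in truth
        ]
    )


def _donor_rate(d: DonorMetadata, config: SimulationConfig, rng: np.random.Generator) -> float:
    if config.mutation_rate is not None:
        return config.mutation_rate
    if d.is_cord_blood:
        return config.cb_mutation_rate
    base = config.plateau_mutation_rate * min(d.age_years, config.plateau_age_years) / config.plateau_age_years
    jitter = float(np.exp(rng.normal(0.0, config.donor_rate_jitter_sd)))
    return min(base * jitter, 0.15)


def _truth_rearrangement(
    read_id: str, donor_id: str, seq: str, truth: TruthRecord, junction_end: int,
    v_len: int,
) -> Rearrangement:
    regions = {
        "CDR1": seq[78:114],
        "FR2": seq[114:165],
        "CDR2": seq[165:195],
        "FR3": seq[195:312],
        "CDR3": seq[312 : junction_end - 3],
    }
    junction_nt = seq[309:junction_end]
    anchors_ok = (
        len(junction_nt) >= 6
        and translate(seq[309:312]) == "C"
        and seq[junction_end - 3 : junction_end] == "TGG"
    )
    productive = False
    if anchors_ok and len(junction_nt) % 3 == 0:
        coding = seq[78:junction_end]
        productive = len(coding) % 3 == 0 and "*" not in translate(coding)
    cdr3 = regions["CDR3"]
    cdr3_aa = translate(cdr3) if cdr3 and len(cdr3) % 3 == 0 else ""
    return Rearrangement(
        read_id=read_id,
        donor_id=donor_id,
        sequence=seq,
        v_call=[truth.v_call],
        d_call=[truth.d_call],
        j_call=[truth.j_call],
        subclass=truth.subclass,
        region_sequences=regions,
        junction_nt=junction_nt,
        cdr3_aa=cdr3_aa,
        productive=productive,
        complete=anchors_ok,
        has_ambiguous_base=False,
        duplicate_count=1,
        n_nucleotides=truth.n_nucleotides,
        junction_deletions=truth.junction_deletions,
        has_indel=False,
        v_germ_start=1,
        v_germ_end=v_len - truth.v_del,
        v_read_start=0,
    )


def emit_repertoire(
    config: SimulationConfig,
    outdir: Optional[str | os.PathLike] = None,
    db: Optional[GermlineDatabase] = None,
) -> SimulatedRepertoire:
    """Generate the full repertoire; fully reproducible from ``config.seed``."""
    config.validate()
    db = db if db is not None else default_germline_db()
    rng = np.random.default_rng(config.seed)
    donors = config.donors if config.donors is not None else default_donors()

    fwd_primer = _rand_nt(rng, config.primer_len)
    rev_primer = _rand_nt(rng, config.primer_len)

    reads: list[RawRead] = []
    truth_records: list[TruthRecord] = []
    rearrangements: list[Rearrangement] = []

    for donor in donors:
        rate = _donor_rate(donor, config, rng)
        lo, hi = ANALYSIS_NT_SPAN
        span = hi - lo + 1
        seen_junctions: dict[int, list[str]] = {}
        for cls in ("IGG", "IGA"):
            for c in range(config.n_clones):
                clone_id = f"{donor.donor_id}_{cls}_c{c:03d}"
                naive, jt = _draw_clone_junction(config, rng, db, seen_junctions)
                junction_end = jt["junction_end"]
                v_len = len(db[jt["v_call"]].sequence)
                size = int(min(rng.zipf(config.clone_size_exponent), config.max_clone_size))

                trunk: list[MutKey] = []
                trunk_seq = naive
                if size > 1 and rate > 0:
                    n_trunk = int(rng.poisson(rate * span * config.trunk_fraction))
                    trunk_seq, trunk = mutate_shm(
                        naive, config, rng, n_mutations=n_trunk
                    )
                founder, member_subs = assign_isotype(
                    size, donor.age_group, cls, config, rng
                )
                used_positions = {p for p, _, _ in trunk}

                for m in range(size):
                    if size == 1:
                        n_priv = int(rng.poisson(rate * span)) if rate > 0 else 0
                    else:
                        n_priv = (
                            int(rng.poisson(rate * span * (1 - config.trunk_fraction)))
                            if rate > 0
                            else 0
                        )
                    member_seq, priv = mutate_shm(
                        trunk_seq, config, rng,
                        n_mutations=n_priv, exclude=used_positions,
                    )
                    used_positions.update(p for p, _, _ in priv)
                    member_muts = sorted(trunk + priv)
                    member_seq = _apply_junction_snps(
                        member_seq, jt, config, rng
                    )
                    member_id = f"{clone_id}_m{m:02d}"
                    for subclass in member_subs[m]:
                        amplicon = member_seq + db.subclass_motifs[subclass] + _rand_nt(rng, 6)
                        dup_group = f"{member_id}_{subclass}"
                        depth = max(
                            int(rng.geometric(1.0 / config.duplicate_depth_mean)),
                            config.duplicate_depth_min,
                        )
                        for copy in range(depth):
                            read_id = f"{donor.donor_id}|{cls}_c{c:03d}_m{m:02d}_{subclass}_{copy}"
                            seq, err_pos = _apply_errors(amplicon, config, rng)
                            t = TruthRecord(
                                read_id=read_id,
                                donor_id=donor.donor_id,
                                clone_id=clone_id,
                                member_id=member_id,
                                duplicate_group=dup_group,
                                subclass=subclass,
                                v_call=jt["v_call"],
                                d_call=jt["d_call"],
                                j_call=jt["j_call"],
                                mutations=member_muts,
                                junction_nt=seq[309:junction_end],
                                v_del=jt["v_del"],
                                d5_del=jt["d5_del"],
                                d3_del=jt["d3_del"],
                                j_del=jt["j_del"],
                                n1=jt["n1"],
                                n2=jt["n2"],
                                is_sequencing_error_read=bool(err_pos),
                                error_positions=err_pos,
                            )
                            truth_records.append(t)
                            rearrangements.append(
                                _truth_rearrangement(
                                    read_id, donor.donor_id, seq, t, junction_end, v_len
                                )
                            )
                            emitted = seq
                            if config.add_primer_flanks:
                                emitted = fwd_primer + seq + rev_primer
                            reads.append(RawRead(read_id=read_id, sequence=emitted))

    repertoire = SimulatedRepertoire(
        config=config,
        reads=reads,
        truth=truth_records,
        rearrangements=rearrangements,
        donors=donors,
    )
    if outdir is not None:
        repertoire.write(outdir)
    return repertoire


def _draw_clone_junction(
    config: SimulationConfig,
    rng: np.random.Generator,
    db: GermlineDatabase,
    seen_junctions: dict[int, list[str]],
) -> tuple[str, dict]:
    """Recombine until the junction is stop-free and (optionally) well
    separated from same-length junctions of earlier clones."""
    from .clonality import junction_hamming

    best = None
    for _ in range(50):
        naive, jt = vdj_recombine(config, rng, db)
        junction = naive[309 : jt["junction_end"]]
        best = (naive, jt)
        if len(junction) % 3 == 0 and "*" in translate(junction):
            continue
        if config.min_interclone_distance > 0:
            near = any(
                junction_hamming(junction, other) < config.min_interclone_distance
                for other in seen_junctions.get(len(junction), ())
            )
            if near:
                continue
        break
    naive, jt = best
    seen_junctions.setdefault(len(naive[309 : jt["junction_end"]]), []).append(
        naive[309 : jt["junction_end"]]
    )
    return naive, jt


def _apply_junction_snps(
    seq: str, jt: dict, config: SimulationConfig, rng: np.random.Generator
) -> str:
    if config.member_junction_snp_mean <= 0:
        return seq
    n = int(min(rng.poisson(config.member_junction_snp_mean), config.member_junction_snp_cap))
    if n == 0:
        return seq
    interior = list(range(312, jt["junction_end"] - 3))
    if not interior:
        return seq
    out = list(seq)
    for pos in rng.choice(interior, size=min(n, len(interior)), replace=False):
        old = out[pos]
        choices = [b for b in NUCLEOTIDES if b != old]
        out[pos] = choices[int(rng.integers(3))]
    return "".join(out)


def _apply_errors(
    seq: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, list[int]]:
    if config.sequencing_error_rate <= 0:
        return seq, []
    k = int(rng.binomial(len(seq), config.sequencing_error_rate))
    if k == 0:
        return seq, []
    out = list(seq)
    positions = sorted(int(p) for p in rng.choice(len(seq), size=k, replace=False))
    for p in positions:
        choices = [b for b in NUCLEOTIDES if b != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return "".join(out), [p + 1 for p in positions]
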