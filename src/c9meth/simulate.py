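"""Synthetic cohort generator for targeted *C9orf72* repeat-expansion reads.

Emulates the statistical structure of a no-amplification targeted HiFi
experiment at the GGGGCC hexanucleotide locus: every individual carries a
short wild-type allele (2-30 units, meiotically stable) and an expanded
allele whose per-read repeat count is somatically mosaic with a right tail;
each read is left flank + repeat tract + right flank, every CG dinucleotide
receives an integer 5mC probability score on the 0-255 scale, and reads carry
pass-count / predicted-accuracy consensus metadata so the QC profiles have
something real to act on.

The default configuration is calibrated to the blood cohort the pipeline is
designed for: 27 individuals (15 ALS, 1 FTD, 11 presymptomatic), 34 blood
samples including 13 longitudinal timepoints over 6 individuals, 4 pedigrees
with 7 paternal transmissions carrying an intergenerational repeat
contraction, and an optional second-tissue (cerebellum) sample set with
shorter, purer, less methylated expansions.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .records import (
    CPG_COLUMNS,
    EXPANDED,
    META_COLUMNS,
    READ_COLUMNS,
    REPEAT_MOTIF,
    TRUTH_COLUMNS,
    WILD_TYPE,
)

# Fixed synthetic flanks (not the GRCh38 sequence): 120 bp each and CpG-rich
# like the real locus (nine CpGs per flank: two inside the outer 30 bp "read
# end" window, seven interior, none within the 25 bp next to the tract so the
# span anchors stay clean). No GGGGCC occurrence, and junctions chosen so
# that joining flank+tract+flank creates no CG across a boundary (left ends
# in A, right starts with T). The 20 bp anchors used for span detection are
# the tract-proximal termini.
LEFT_FLANK = (
    "GTTATACTTGCGTACAGCTATTTGGGCGGCAACGCGGTCCAACTAATAAGGTTTTGTCGA"
    "CGGGAACGCTTAGGGCGGCAGTCCAGAAAATTGCGTGTGGTGGACTGGTGATGCCCAGTA"
)
RIGHT_FLANK = (
    "TAGCCACTTTACTACAAGGTAGAGAGATAGCTCTGGGGATTCGTCACGTACGCACTCCGT"
    "CCAATGGCCAGTGAGGGGCGCACCGCTCGCCTCTCCCGTCCACTGACTTGTGCGATGTAG"
)

ANCHOR_LENGTH = 20


def default_anchors(flank_length: int = 120) -> tuple[str, str]:
    """Tract-proximal 20 bp termini of the synthetic flanks."""
    left = LEFT_FLANK[-flank_length:]
    right = RIGHT_FLANK[:flank_length]
    return left[-ANCHOR_LENGTH:], right[:ANCHOR_LENGTH]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``seed`` is mandatory: the generator refuses to run without one so every
    fixture is reproducible byte for byte.
    """

    seed: Optional[int] = None
    n_individuals: int = 27
    wt_repeat_range: tuple[int, int] = (2, 30)
    #: If set, every individual's expanded allele has this modal repeat count;
    #: if None, modal lengths are drawn from the age-linked cohort model.
    expanded_modal_length: Optional[int] = None
    #: Scale of the half-normal right tail of per-read repeat counts
    #: (fraction of the modal length).
    mosaicism_dispersion: float = 0.12
    #: Base probability per repeat unit of a single-base interruption; the
    #: effective per-unit probability grows with tract size (see
    #: :func:`_interruption_probability`).
    interruption_rate: float = 0.005
    flank_length: int = 120
    #: Mean methylation fraction of flank CpGs near the read ends (0-1).
    #: Flank CpGs interior to the end window follow the allele's tract level
    #: (locus methylation extends into the flanks), which keeps wild-type
    #: per-read proportions in the observed 15-20% band regardless of the
    #: wild-type tract size.
    flank_cpg_meth_level: float = 0.8
    #: Width in bases of the "read end" window of each flank whose CpGs are
    #: drawn at flank_cpg_meth_level; set >= flank_length to put every flank
    #: CpG at that level.
    flank_end_window: int = 30
    #: Expanded-allele mean methylation fraction per read is
    #: clamp(intercept + slope * repeat_count) plus individual jitter.
    expansion_meth_slope: float = 1.0e-4
    expansion_meth_intercept: float = 0.22
    #: Mean methylation fraction of wild-type tract CpGs.
    wt_meth_level: float = 0.08
    #: "bernoulli": each CpG draws a methylated/unmethylated state at its mean
    #: fraction and its score is the corresponding level plus Gaussian noise.
    #: "mean": score = 255 * mean fraction plus Gaussian noise.
    score_model: str = "bernoulli"
    score_noise_sd: float = 25.0
    bernoulli_low: float = 20.0
    bernoulli_high: float = 235.0
    reads_per_allele_range: tuple[int, int] = (6, 12)
    #: n_passes = 1 + Poisson(pass_count_mean - 1).
    pass_count_mean: float = 12.0
    #: predicted accuracy = 1 - accuracy_scale * exp(-accuracy_decay * passes)
    #: * Uniform(0.5, 1.5), clipped to [0, 1].
    accuracy_decay: float = 0.5
    accuracy_scale: float = 0.3
    #: Probability a read fails to span one flank (truncated molecule).
    truncation_rate: float = 0.08
    #: SD of the per-individual offset added to mean methylation fractions.
    individual_meth_jitter_sd: float = 0.02
    # Cohort structure toggles.
    include_longitudinal: bool = True
    include_pedigrees: bool = True
    include_cerebellum: bool = True
    cerebellum_length_factor: float = 0.7
    cerebellum_meth_offset: float = -0.12
    # Age model and age-length coupling (repeats per year of age).
    length_per_year: float = 60.0
    length_age_offset: float = 22.0
    length_noise_sd: float = 250.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("SimulationConfig.seed is required for reproducibility")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        lo, hi = self.wt_repeat_range
        if not (2 <= lo <= hi <= 30):
            raise ValueError("wt_repeat_range must lie within [2, 30]")
        if self.expanded_modal_length is not None and self.expanded_modal_length < 64:
            raise ValueError("expanded_modal_length must be >= 64")
        for name in ("interruption_rate", "truncation_rate", "flank_cpg_meth_level",
                     "wt_meth_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        rlo, rhi = self.reads_per_allele_range
        if not (1 <= rlo <= rhi):
            raise ValueError("reads_per_allele_range must be a positive interval")
        if self.score_model not in ("bernoulli", "mean"):
            raise ValueError("score_model must be 'bernoulli' or 'mean'")
        if self.mosaicism_dispersion < 0 or self.score_noise_sd < 0:
            raise ValueError("dispersion and noise parameters must be non-negative")
        if self.flank_length < ANCHOR_LENGTH or self.flank_length > len(LEFT_FLANK):
            raise ValueError(
                f"flank_length must be in [{ANCHOR_LENGTH}, {len(LEFT_FLANK)}]"
            )


@dataclass
class SimulatedCohort:
    """The four tables produced by :func:`simulate_cohort`."""

    reads: pd.DataFrame
    cpg: pd.DataFrame
    truth: pd.DataFrame
    meta: pd.DataFrame


# ---------------------------------------------------------------------------
# individual-level cohort model
# ---------------------------------------------------------------------------

def _interruption_probability(rate: float, n_units: int) -> float:
    """Effective per-unit interruption probability for a tract of ``n_units``.

    Interruptions accrue with tract size (longer expansions are less pure),
    so the per-unit probability scales linearly with the unit count.
    """
    return float(np.clip(rate * n_units / 100.0, 0.0, 0.5))


def _draw_individuals(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_individuals
    ids = [f"IND{i + 1:02d}" for i in range(n)]

    # Diagnosis groups in the cohort's proportions (presymptomatic ~41%, one
    # FTD case once the cohort is large enough, the rest ALS).
    n_presym = max(1, round(0.41 * n)) if n >= 3 else 0
    n_ftd = 1 if n >= 10 else 0
    n_als = n - n_presym - n_ftd
    groups = ["ALS"] * n_als + ["FTD"] * n_ftd + ["presymptomatic"] * n_presym

    sex = np.where(rng.random(n) < 0.59, "F", "M")

    age = np.empty(n)
    onset = np.full(n, np.nan)
    for i, g in enumerate(groups):
        if g == "presymptomatic":
            age[i] = float(np.clip(rng.normal(39.0, 8.0), 25.0, 55.0))
        else:
            age[i] = float(np.clip(rng.normal(62.0, 7.0), 45.0, 78.0))
            onset[i] = max(25.0, age[i] - abs(rng.normal(2.0, 1.5)))

    # Expanded modal length: age-linked with noise, giving the cohort its
    # positive length-age correlation; an explicit expanded_modal_length
    # overrides the model (used for controlled experiments).
    if cfg.expanded_modal_length is not None:
        modal = np.full(n, float(cfg.expanded_modal_length))
    else:
        modal = np.clip(
            cfg.length_per_year * (age - cfg.length_age_offset)
            + rng.normal(0.0, cfg.length_noise_sd, size=n),
            300.0,
            3400.0,
        )

    wt_lo, wt_hi = cfg.wt_repeat_range
    wt_count = rng.integers(wt_lo, wt_hi + 1, size=n)

    df = pd.DataFrame(
        {
            "individual_id": ids,
            "group": groups,
            "sex": sex,
            "age_at_collection": np.round(age, 2),
            "age_at_onset": np.round(onset, 2),
            "modal_repeats": modal,
            "wt_repeats": wt_count,
            "father_id": [""] * n,
            "pedigree_id": [""] * n,
        }
    )

    # Pedigrees: 4 fathers (oldest ALS cases) and 7 presymptomatic offspring
    # (2+2+2+1), each transmission carrying a repeat contraction large enough
    # to shift mean expansion methylation well past the 10%-point rule.
    if cfg.include_pedigrees and cfg.expanded_modal_length is None and n_als >= 4 and n_presym >= 7:
        als_idx = [i for i, g in enumerate(groups) if g == "ALS"]
        presym_idx = [i for i, g in enumerate(groups) if g == "presymptomatic"]
        fathers = sorted(als_idx, key=lambda i: -age[i])[:4]
        offspring = presym_idx[:7]
        ped_sizes = [2, 2, 2, 1]
        k = 0
        for p, (f_idx, size) in enumerate(zip(fathers, ped_sizes), start=1):
            df.loc[f_idx, "modal_repeats"] = max(df.loc[f_idx, "modal_repeats"], 2600.0)
            df.loc[f_idx, "pedigree_id"] = f"PED{p}"
            for _ in range(size):
                c_idx = offspring[k]
                k += 1
                contraction = rng.uniform(1800.0, 2200.0)
                df.loc[c_idx, "modal_repeats"] = max(
                    300.0, df.loc[f_idx, "modal_repeats"] - contraction
                )
                df.loc[c_idx, "father_id"] = ids[f_idx]
                df.loc[c_idx, "pedigree_id"] = f"PED{p}"

    # Per-individual methylation jitter, shared across that individual's
    # samples so longitudinal stability reflects biology, not resampling.
    df["meth_jitter"] = rng.normal(0.0, cfg.individual_meth_jitter_sd, size=n)

    # Promoter methylation: low in most carriers, elevated in the most
    # methylated expansions (moderate positive coupling with expansion
    # methylation); the hypermethylation flag is a fixed 5% cutoff.
    f_ind = np.clip(
        cfg.expansion_meth_intercept
        + cfg.expansion_meth_slope * df["modal_repeats"].to_numpy()
        + df["meth_jitter"].to_numpy(),
        0.02,
        0.98,
    )
    promoter = np.clip(
        1.5 * np.exp(rng.normal(0.0, 0.7, size=n))
        + 80.0 * np.maximum(0.0, f_ind - 0.42)
        + rng.normal(0.0, 1.0, size=n),
        0.1,
        60.0,
    )
    df["promoter_methylation_pct"] = np.round(promoter, 2)
    df["promoter_hypermethylated"] = promoter >= 5.0

    # Southern-blot style external length estimates (main band and smear).
    df["southern_repeats"] = np.round(
        np.clip(df["modal_repeats"] * 1.25 * (1.0 + rng.normal(0.0, 0.25, size=n)), 200, 6000)
    )
    df["southern_smear"] = np.round(
        np.clip(0.3 * df["modal_repeats"] * (1.0 + rng.normal(0.0, 0.4, size=n)), 50, 3000)
    )
    return df


def _sample_plan(cfg: SimulationConfig, ind: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One row per (individual, timepoint, tissue) sample to simulate."""
    rows = []
    n = len(ind)

    # Longitudinal structure: 6 individuals, 13 timepoints in total; the first
    # four are stable, the last two drift (driven by a modal-length shift so
    # length and methylation move together).
    longi: dict[int, list[tuple[float, float]]] = {}
    if cfg.include_longitudinal and cfg.expanded_modal_length is None and n >= 10:
        candidates = [i for i in range(n) if ind.loc[i, "father_id"] == ""][:6]
        for j, i in enumerate(candidates):
            if j < 4:  # stable: <10%-point methylation change
                extra = [(rng.uniform(1.5, 4.0), rng.uniform(-60.0, 60.0))]
                if j == 0:  # one individual contributes three timepoints
                    extra.append((extra[0][0] + rng.uniform(1.5, 4.0), rng.uniform(-60.0, 60.0)))
            else:  # variable: modal shift of ~1400 units => ~0.14 shift
                extra = [(rng.uniform(1.5, 4.0), 1400.0)]
            longi[i] = extra

    for i in range(n):
        iid = ind.loc[i, "individual_id"]
        rows.append((iid, 0, 0.0, "blood", float(ind.loc[i, "modal_repeats"])))
        for t, (dt, dmodal) in enumerate(longi.get(i, []), start=1):
            rows.append(
                (iid, t, round(float(dt), 2), "blood",
                 float(np.clip(ind.loc[i, "modal_repeats"] + dmodal, 300.0, 4000.0)))
            )
        if cfg.include_cerebellum:
            rows.append(
                (iid, 0, 0.0, "cerebellum",
                 float(max(210.0, ind.loc[i, "modal_repeats"] * cfg.cerebellum_length_factor)))
            )
    plan = pd.DataFrame(
        rows, columns=["individual_id", "timepoint", "timepoint_years", "tissue", "modal_repeats"]
    )
    return plan


# ---------------------------------------------------------------------------
# read-level generation
# ---------------------------------------------------------------------------

_SUB_CHOICES = {
    "G": np.array(list("ACT")),
    "C": np.array(list("AGT")),
}


def _interrupt_unit(unit: str, rng: np.random.Generator) -> str:
    """Apply one single-base substitution or deletion to a repeat unit."""
    pos = int(rng.integers(0, len(unit)))
    if rng.random() < 0.5:  # substitution
        base = unit[pos]
        new = str(rng.choice(_SUB_CHOICES[base]))
        return unit[:pos] + new + unit[pos + 1:]
    return unit[:pos] + unit[pos + 1:]  # deletion


def _build_tract(n_units: int, p_int: float, rng: np.random.Generator) -> tuple[str, list[int]]:
    if p_int <= 0.0:
        return REPEAT_MOTIF * n_units, []
    n_int = int(rng.binomial(n_units, p_int))
    if n_int == 0:
        return REPEAT_MOTIF * n_units, []
    where = sorted(int(x) for x in rng.choice(n_units, size=n_int, replace=False))
    units = [REPEAT_MOTIF] * n_units
    for u in where:
        units[u] = _interrupt_unit(REPEAT_MOTIF, rng)
    return "".join(units), where


def _find_cg_positions(seq: str) -> list[int]:
    out = []
    i = seq.find("CG")
    while i != -1:
        out.append(i)
        i = seq.find("CG", i + 1)
    return out


def _scores_for(levels: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.score_model == "bernoulli":
        state = rng.random(levels.size) < levels
        mean = np.where(state, cfg.bernoulli_high, cfg.bernoulli_low)
    else:
        mean = 255.0 * levels
    noise = rng.normal(0.0, cfg.score_noise_sd, size=levels.size) if cfg.score_noise_sd > 0 else 0.0
    return np.clip(np.rint(mean + noise), 0, 255).astype(int)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate reads, CpG calls, ground truth and sample metadata.

    Deterministic for a fixed ``config.seed``; raises ``ValueError`` on an
    invalid configuration (including a missing seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    ind = _draw_individuals(config, rng)
    plan = _sample_plan(config, ind, rng)
    ind_by_id = ind.set_index("individual_id")

    left_flank = LEFT_FLANK[-config.flank_length:]
    right_flank = RIGHT_FLANK[:config.flank_length]

    read_rows: list[tuple] = []
    cpg_read_ids: list[str] = []
    cpg_pos: list[np.ndarray] = []
    cpg_scores: list[np.ndarray] = []
    truth_rows: list[tuple] = []
    meta_rows: list[tuple] = []

    rlo, rhi = config.reads_per_allele_range
    for row in plan.itertuples(index=False):
        iid = row.individual_id
        info = ind_by_id.loc[iid]
        sample_id = f"{iid}_T{row.timepoint}_{row.tissue}"
        meth_offset = config.cerebellum_meth_offset if row.tissue == "cerebellum" else 0.0
        disp = config.mosaicism_dispersion * (0.6 if row.tissue == "cerebellum" else 1.0)
        int_rate = config.interruption_rate * (0.5 if row.tissue == "cerebellum" else 1.0)

        serial = 0
        for allele in (WILD_TYPE, EXPANDED):
            n_reads = int(rng.integers(rlo, rhi + 1))
            for _ in range(n_reads):
                if allele == WILD_TYPE:
                    n_units = int(info["wt_repeats"])
                    tract_level = config.wt_meth_level + info["meth_jitter"] + meth_offset
                else:
                    n_units = max(1, int(round(row.modal_repeats * (1.0 + abs(rng.normal(0.0, disp))))))
                    tract_level = (
                        config.expansion_meth_intercept
                        + config.expansion_meth_slope * n_units
                        + info["meth_jitter"]
                        + meth_offset
                    )
                tract_level = float(np.clip(tract_level, 0.02, 0.98))
                p_int = _interruption_probability(int_rate, n_units)
                tract, interruptions = _build_tract(n_units, p_int, rng)

                spans_left = spans_right = True
                lf, rf = left_flank, right_flank
                if config.truncation_rate > 0 and rng.random() < config.truncation_rate:
                    cut = rng.random()  # fraction of tract lost with the flank
                    n_cut = int(0.5 * cut * len(tract))
                    if rng.random() < 0.5:
                        spans_left, lf = False, ""
                        tract = tract[n_cut:]
                    else:
                        spans_right, rf = False, ""
                        tract = tract[: len(tract) - n_cut] if n_cut else tract

                seq = lf + tract + rf
                tract_start, tract_end = len(lf), len(lf) + len(tract)

                read_id = f"{sample_id}/{serial:04d}"
                serial += 1
                n_passes = int(1 + rng.poisson(max(config.pass_count_mean - 1.0, 0.0)))
                accuracy = float(
                    np.clip(
                        1.0
                        - config.accuracy_scale
                        * math.exp(-config.accuracy_decay * n_passes)
                        * rng.uniform(0.5, 1.5),
                        0.0,
                        1.0,
                    )
                )

                positions = np.array(_find_cg_positions(seq), dtype=int)
                if positions.size:
                    flank_level = float(np.clip(config.flank_cpg_meth_level + meth_offset, 0.02, 0.98))
                    # only CpGs inside the read-end windows of an intact flank
                    # take the (high) flank level; interior flank CpGs follow
                    # the allele's tract level
                    w = config.flank_end_window
                    terminal = (positions < min(w, len(lf))) | (
                        positions >= len(seq) - min(w, len(rf))
                    )
                    levels = np.where(terminal, flank_level, tract_level)
                    scores = _scores_for(levels, config, rng)
                    cpg_read_ids.extend([read_id] * positions.size)
                    cpg_pos.append(positions)
                    cpg_scores.append(scores)

                read_rows.append(
                    (read_id, iid, sample_id, seq, n_passes, round(accuracy, 5),
                     spans_left, spans_right)
                )
                truth_rows.append(
                    (read_id, iid, allele, n_units, len(interruptions),
                     ",".join(map(str, interruptions)), tract_level,
                     float(np.clip(config.flank_cpg_meth_level + meth_offset, 0.02, 0.98)),
                     spans_left, spans_right)
                )

        meta_rows.append(
            (sample_id, iid, info["group"], info["sex"], row.tissue,
             float(row.timepoint_years),
             round(float(info["age_at_collection"]) + float(row.timepoint_years), 2),
             info["age_at_onset"], info["promoter_methylation_pct"],
             bool(info["promoter_hypermethylated"]), info["southern_repeats"],
             info["southern_smear"], info["father_id"], info["pedigree_id"],
             int(info["wt_repeats"]))
        )

    reads = pd.DataFrame(read_rows, columns=READ_COLUMNS)
    if cpg_pos:
        cpg = pd.DataFrame(
            {
                "read_id": cpg_read_ids,
                "read_pos_0based": np.concatenate(cpg_pos),
                "score": np.concatenate(cpg_scores),
            }
        )
    else:
        cpg = pd.DataFrame(columns=CPG_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    return SimulatedCohort(reads=reads, cpg=cpg, truth=truth, meta=meta)


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
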