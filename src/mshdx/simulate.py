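"""Synthetic uptake data with known ground truth.

Forward-simulates everything the analysis pipeline consumes: per-peptide
deuterium-uptake tables (intrinsic rates slowed by a per-residue protection
factor, scaled by a back-exchange retention fraction, plus replicate
noise), maximally deuterated reference tables, replicate-repeatability
panels, and protein-digest workloads.  All randomness flows from the single
seed stored in :class:`SimulationTruth`.

The default study conditions are those of the instrument-validation
experiments: the five standard peptides, labeling at pD_read 7.06 and
23 C in ~95% D2O, a 15-point exposure schedule from 50 ms to 300 s, three
replicates, and a homoscedastic per-replicate noise SD of 0.084 Da (chosen
so that the 95% confidence interval of a 270-replicate mean is ~ +/-0.01 Da,
i.e. ~3% relative dispersion of a few-Da signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intrinsic import residue_intrinsic_rates, theoretical_max_uptake
from .peptides import STANDARD_PEPTIDES, LabelingConditions, PeptideSpec
from .series import UptakeSeries

#: the 15-point millisecond-to-minutes exposure schedule (seconds)
PRINTED_SCHEDULE = (
    0.05, 0.1, 0.15, 0.20, 0.25, 0.35, 0.5, 0.75, 1.0, 2.5, 5.0, 15.0, 30.0, 60.0, 300.0,
)

#: per-replicate noise SD (Da) giving a ~ +/-0.01 Da 95% CI at n = 270
DEFAULT_NOISE_SD = 0.084


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for a synthetic HDX study.

    ``ln_pf`` maps peptide name -> scalar or per-residue array of ln
    protection factors (scalar = uniform protection); ``retention`` maps
    peptide name -> back-exchange retention fraction in (0, 1] (a plain
    float applies to all peptides).
    """

    peptides: dict = field(default_factory=lambda: dict(STANDARD_PEPTIDES))
    ln_pf: dict | float = 0.0
    conditions: LabelingConditions = field(default_factory=LabelingConditions)
    retention: dict | float = 0.85
    noise_sd: float = DEFAULT_NOISE_SD
    exposures: tuple = PRINTED_SCHEDULE
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        exposures = tuple(float(t) for t in self.exposures)
        object.__setattr__(self, "exposures", exposures)
        if any(b <= a for a, b in zip(exposures, exposures[1:])):
            raise ValueError("exposure schedule must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        for name in self.peptides:
            r = self.retention_for(name)
            if not 0.0 < r <= 1.0:
                raise ValueError(f"retention {r} for {name!r} not in (0, 1]")

    def ln_pf_for(self, name: str) -> np.ndarray | float:
        if isinstance(self.ln_pf, dict):
            return self.ln_pf.get(name, 0.0)
        return self.ln_pf

    def retention_for(self, name: str) -> float:
        if isinstance(self.retention, dict):
            return float(self.retention.get(name, 1.0))
        return float(self.retention)


def true_uptake_curve(
    peptide: PeptideSpec,
    truth: SimulationTruth,
    name: str,
    times,
) -> np.ndarray:
    """Noise-free protected uptake (before back-exchange), Da."""
    rates = residue_intrinsic_rates(peptide, truth.conditions)
    k = rates.rates.copy()
    ln_pf = truth.ln_pf_for(name)
    pf = np.exp(np.broadcast_to(np.asarray(ln_pf, dtype=float), k.shape))
    k_slow = np.where(k > 0, k / pf, 0.0)
    t = np.asarray(times, dtype=float)
    inc = k_slow[k_slow > 0]
    if inc.size == 0:
        return np.zeros_like(t)
    return truth.conditions.d2o_fraction * np.sum(
        1.0 - np.exp(-np.outer(t, inc)), axis=1
    )


def generate_uptake_tables(
    truth: SimulationTruth,
) -> tuple[dict[str, UptakeSeries], dict[str, UptakeSeries]]:
    """Observed and maxD-reference uptake tables for every peptide in truth.

    observed = retention * true_uptake + N(0, sd);
    maxD     = retention * (f_D2O * Q)  + N(0, sd).
    Negative noise excursions are clamped at 0 (uptake is a mass shift).
    Reproducible from ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    t = np.asarray(truth.exposures)
    observed: dict[str, UptakeSeries] = {}
    maxd: dict[str, UptakeSeries] = {}
    for name, pep in truth.peptides.items():
        retention = truth.retention_for(name)
        clean = retention * true_uptake_curve(pep, truth, name, t)
        noise = truth.noise_sd * rng.standard_normal((t.size, truth.n_replicates))
        observed[name] = UptakeSeries(
            pep,
            t,
            np.clip(clean[:, None] + noise, 0.0, None),
            units="Da",
            state="labeled",
            protein=name,
        )
        max_up = retention * theoretical_max_uptake(pep, truth.conditions.d2o_fraction)
        noise = truth.noise_sd * rng.standard_normal((t.size, truth.n_replicates))
        maxd[name] = UptakeSeries(
            pep,
            t,
            np.clip(max_up + noise, 0.0, None),
            units="Da",
            is_maxD_reference=True,
            state="maxD",
            protein=name,
        )
    return observed, maxd


@dataclass(frozen=True)
class ReplicateSummary:
    """Summary of a replicate-repeatability panel."""

    mean: float
    sd: float
    ci95_halfwidth: float
    relative_dispersion: float  # sd / mean
    n: int


def generate_replicate_study(
    peptide: PeptideSpec,
    n_replicates: int,
    time: float,
    truth: SimulationTruth,
    name: str = "peptide",
) -> tuple[np.ndarray, ReplicateSummary]:
    """Deviations from the mean for ``n_replicates`` measurements at one
    labeling time, plus a (mean, SD, 95% CI) summary.

    Emulates the repeatability panels used to validate labeling precision
    (hundreds of technical replicates at a 100 ms mixing time).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(truth.seed)
    clean = truth.retention_for(name) * float(
        true_uptake_curve(peptide, truth, name, [time])[0]
    )
    values = clean + truth.noise_sd * rng.standard_normal(n_replicates)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    ci = 1.959964 * sd / np.sqrt(n_replicates)
    rel = sd / mean if mean != 0 else np.inf
    return values - mean, ReplicateSummary(mean, sd, float(ci), float(rel), n_replicates)


def generate_protein_digest(
    n_peptides: int = 270,
    protein_length: int = 900,
    seed: int = 0,
    mean_peptide_length: float = 12.0,
) -> tuple[str, list[PeptideSpec]]:
    """A protein-digest-scale workload: a random dummy sequence and ~n
    overlapping peptide segments mirroring a large-enzyme bottom-up map.

    Workload shape only (peptide count, overlap, coverage) -- the sequence
    carries no biological meaning.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNQRSTVWY"))  # no Pro: keep Q > 0 likely
    seq_arr = rng.choice(alphabet, size=protein_length)
    # sprinkle some prolines at ~4% to exercise exclusion bookkeeping
    n_pro = protein_length // 25
    seq_arr[rng.choice(protein_length, size=n_pro, replace=False)] = "P"
    sequence = "".join(seq_arr)
    peptides = []
    for _ in range(n_peptides):
        length = int(np.clip(rng.poisson(mean_peptide_length), 5, 40))
        start = int(rng.integers(1, protein_length - length + 1))
        peptides.append(
            PeptideSpec(
                sequence[start - 1 : start - 1 + length],
                start_residue=start,
            )
        )
    return sequence, peptides


def coverage_fraction(protein_length: int, peptides: list[PeptideSpec]) -> float:
    """Fraction of protein residues covered by at least one peptide."""
    covered = np.zeros(protein_length, dtype=bool)
    for p in peptides:
        covered[p.start_residue - 1 : p.end_residue] = True
    return float(np.mean(covered))
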