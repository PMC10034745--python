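"""End-to-end pipeline: uptake CSV -> corrected uptake, fits, ln(Pf)."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .backexchange import correct_uptake, estimate_backexchange, normalize_percent
from .intrinsic import (
    intrinsic_uptake_curve,
    residue_intrinsic_rates,
    theoretical_max_uptake,
)
from .io import read_state_csv, write_state_csv
from .kinetics import (
    ensemble_ln_pf,
    fit_stretched_exponential,
    protection_factors,
    select_model,
)
from .peptides import LabelingConditions
from .series import UptakeSeries


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one analysis run."""

    uptake_csv: str
    out_dir: str
    maxd_state: str = "maxD"
    exposure_units: str = "s"
    conditions: LabelingConditions = field(default_factory=LabelingConditions)
    max_phases: int = 3
    alpha: float = 0.05
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def hash(self) -> str:
        payload = json.dumps(
            {
                "uptake_csv": str(self.uptake_csv),
                "maxd_state": self.maxd_state,
                "exposure_units": self.exposure_units,
                "pD_read": self.conditions.pD_read,
                "temperature": self.conditions.temperature,
                "d2o_fraction": self.conditions.d2o_fraction,
                "max_phases": self.max_phases,
                "alpha": self.alpha,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        cond = data.pop("conditions", {})
        return cls(conditions=LabelingConditions(**cond), **data)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def analyze_peptide(
    observed: UptakeSeries,
    maxd: UptakeSeries | None,
    cond: LabelingConditions,
    max_phases: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Full per-peptide analysis: back-exchange, fit, protection factors."""
    pep = observed.peptide
    result: dict = {
        "sequence": pep.sequence,
        "start": pep.start_residue,
        "end": pep.end_residue,
        "n_exchangeable": pep.n_exchangeable,
        "status": "fitted",
    }
    if pep.n_exchangeable == 0:
        result["status"] = "uninformative"
        result["reason"] = "no exchangeable amides (Q = 0)"
        return result

    rates = residue_intrinsic_rates(pep, cond)
    theo_max = theoretical_max_uptake(pep, cond.d2o_fraction)
    result["theoretical_max_Da"] = theo_max

    corrected = observed
    if maxd is not None:
        bx = estimate_backexchange(maxd, theo_max)
        corrected = correct_uptake(observed, bx, theoretical_max=theo_max)
        result["backexchange"] = {
            "retention": bx.retention,
            "slope_per_s": bx.slope_per_s,
            "r_squared": bx.r_squared,
            "p_value": bx.p_value,
        }

    fit = select_model(corrected, alpha=alpha, max_phases=max_phases, q_total=theo_max)
    result["fit"] = {
        "n_phases": fit.n_phases,
        "amplitudes_Da": fit.amplitudes.tolist(),
        "rates_per_s": fit.rates.tolist(),
        "betas": fit.betas.tolist(),
        "rss": fit.rss,
        "r_squared": fit.r_squared,
    }
    result["status"] = fit.status
    if fit.status != "fitted":
        return result

    # fit the theoretical intrinsic curve in the same manner, then form
    # protection factors: per-phase detail from a same-phase-count pairing,
    # and a robust peptide-averaged value from matched single-phase fits
    intr_curve = intrinsic_uptake_curve(rates, corrected.exposures)
    intr_series = UptakeSeries(
        pep, corrected.exposures, intr_curve[:, None], state="intrinsic"
    )
    try:
        result["ln_pf_peptide"] = ensemble_ln_pf(
            corrected, intr_series, q_total=theo_max
        )
    except ValueError as exc:
        result["ln_pf_peptide"] = None
        result["ln_pf_error"] = str(exc)
    try:
        # densify the noiseless intrinsic curve so 2-3-phase fits are
        # identifiable regardless of the experimental schedule length
        t_dense = np.geomspace(
            corrected.exposures[0], corrected.exposures[-1], 30
        )
        intr_dense = UptakeSeries(
            pep,
            t_dense,
            intrinsic_uptake_curve(rates, t_dense)[:, None],
            state="intrinsic",
        )
        intr_fit = fit_stretched_exponential(
            intr_dense, fit.n_phases, q_total=theo_max
        )
        pf = protection_factors(fit, intr_fit)
        result["intrinsic_fit"] = {
            "rates_per_s": intr_fit.rates.tolist(),
            "amplitudes_Da": intr_fit.amplitudes.tolist(),
            "betas": intr_fit.betas.tolist(),
            "r_squared": intr_fit.r_squared,
        }
        result["ln_pf"] = pf.ln_pf.tolist()
    except ValueError as exc:
        result["ln_pf"] = None
        result["ln_pf_error"] = str(exc)
    return result


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the whole analysis and write the result bundle to ``out_dir``.

    Outputs: ``fits.json`` (per-peptide parameters and ln Pf),
    ``corrected.csv`` (back-exchange-corrected uptake, Da),
    ``percent.csv`` (normalized percent uptake), optional plots, and
    ``run.log``.  Deterministic given the configuration; ``fits.json`` is
    byte-identical across reruns.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, diagnostics = read_state_csv(
        cfg.uptake_csv, exposure_units=cfg.exposure_units, maxd_state=cfg.maxd_state
    )
    observed = [s for s in series if not s.is_maxD_reference]
    maxd_by_pep = {
        (s.peptide.sequence, s.peptide.start_residue): s
        for s in series
        if s.is_maxD_reference
    }
    if not observed:
        raise ValueError("no valid labeled uptake series in input")

    results = {}
    corrected_out: list[UptakeSeries] = []
    percent_out: list[UptakeSeries] = []
    for s in observed:
        key = (s.peptide.sequence, s.peptide.start_residue)
        maxd = maxd_by_pep.get(key)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = analyze_peptide(
                s, maxd, cfg.conditions, max_phases=cfg.max_phases, alpha=cfg.alpha
            )
        name = f"{s.protein}:{s.peptide.sequence}"
        results[name] = res
        if res.get("backexchange") and res["status"] != "uninformative":
            bx_retention = res["backexchange"]["retention"]
            corr = s.with_uptake(s.uptake / bx_retention, state="corrected")
            corrected_out.append(corr)
            percent_out.append(
                normalize_percent(corr, res["theoretical_max_Da"])
            )
        if cfg.make_plots and res["status"] == "fitted":
            from .kinetics import StretchedExpModel
            from .plots import plot_uptake

            fit = StretchedExpModel(
                res["fit"]["n_phases"],
                np.array(res["fit"]["amplitudes_Da"]),
                np.array(res["fit"]["rates_per_s"]),
                np.array(res["fit"]["betas"]),
                res["fit"]["rss"],
                res["fit"]["r_squared"],
                0,
            )
            rates = residue_intrinsic_rates(s.peptide, cfg.conditions)
            plot_uptake(
                s, fit, rates, title=name,
                path=out_dir / f"{s.protein}_{s.peptide.start_residue}.svg",
            )

    bundle = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_peptides": len(results),
        "n_row_diagnostics": len(diagnostics),
        "peptides": results,
    }
    (out_dir / "fits.json").write_text(
        json.dumps(_round_floats(bundle), indent=2, sort_keys=True)
    )
    if corrected_out:
        write_state_csv(corrected_out, out_dir / "corrected.csv")
        write_state_csv(percent_out, out_dir / "percent.csv")
    log_lines = [
        f"mshdx {__version__}",
        f"config hash {cfg.hash()}",
        f"seed {cfg.seed}",
        f"{len(results)} peptide(s) analyzed; "
        f"{sum(1 for r in results.values() if r['status'] == 'fitted')} fitted",
    ] + [f"row {d.row}: {d.message}" for d in diagnostics]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return bundle
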