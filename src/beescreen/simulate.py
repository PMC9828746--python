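"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's input families:

* ``gen_use_records`` — per-application use-report records with
  log-normal application rates (heavy right tail, as in self-reported
  registries), a controlled fraction of injected outliers strictly above
  the analytic IQR fence of the clean distribution, and ×100
  multiplier-style unit-entry errors, with truth labels returned for
  recovery testing;
* ``gen_residue_study`` — triplicate residue concentrations per matrix
  and sampling day following first-order decay from an initial deposit,
  with log-normal replicate noise and censoring below the per-matrix
  minimum detectable limit;
* ``gen_dose_response`` — quantal mortality from a log-logistic
  tolerance distribution.

Everything is driven by one integer seed; identical configurations give
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .endpoints import QuantalDoseResponse

__all__ = [
    "SimConfig",
    "analytic_fence",
    "gen_use_records",
    "gen_residue_study",
    "gen_dose_response",
]

#: Default per-matrix residue-decay settings: initial concentration C0
#: (mg/kg), first-order decay rate k (1/day), LOQ and MDL (mg/kg).
#: Pollen-type matrices peak one to two orders of magnitude above nectar,
#: as observed in foliar-spray studies; larvae sit near the nectar level.
DEFAULT_MATRIX_PARAMS: dict[str, dict[str, float]] = {
    "forager_pollen": {"c0": 60.0, "k": 0.35, "loq": 0.1, "mdl": 0.015},
    "bee_bread": {"c0": 25.0, "k": 0.25, "loq": 0.1, "mdl": 0.010},
    "forager_nectar": {"c0": 1.5, "k": 0.30, "loq": 0.1, "mdl": 0.014},
    "stored_nectar": {"c0": 0.15, "k": 0.20, "loq": 0.1, "mdl": 0.014},
    "larvae": {"c0": 0.5, "k": 0.25, "loq": 0.1, "mdl": 0.020},
    "wax": {"c0": 8.0, "k": 0.10, "loq": 0.1, "mdl": 0.015},
    "whole_bees": {"c0": 5.0, "k": 0.30, "loq": 0.1, "mdl": 0.017},
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration for all three generators (one seed drives them all)."""

    seed: int = 0
    # use records
    n_records: int = 1000
    rate_mu: float = 0.0  # log kg/ha
    rate_sigma: float = 0.5
    outlier_fraction: float = 0.01
    outlier_multiplier: float = 3.0  # outliers drawn in [1.5, multiplier] x fence
    unit_error_fraction: float = 0.005
    unit_error_factor: float = 100.0
    neat_fraction: float = 0.3
    # residue study
    matrix_params: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_MATRIX_PARAMS
    )
    days: tuple[int, ...] = (0, 1, 4, 7, 10)
    replicates: int = 3
    replicate_cv: float = 0.2
    # dose-response
    ld50: float = 50.0
    slope: float = 4.0
    doses: tuple[float, ...] = (6.25, 12.5, 25.0, 50.0, 100.0)
    n_per_dose: int = 30  # three replicate cages of ten bees, pooled
    control_n: int = 30
    control_mortality: float = 0.0

    def __post_init__(self):
        for name in ("outlier_fraction", "unit_error_fraction", "neat_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.rate_sigma <= 0 and self.outlier_fraction > 0:
            raise ValueError(
                "degenerate rate distribution (sigma = 0) has a point-mass "
                "fence; outlier injection is undefined"
            )
        if self.rate_sigma < 0 or self.replicate_cv < 0:
            raise ValueError("scales must be non-negative")


def analytic_fence(mu: float, sigma: float) -> float:
    """IQR upper fence of the log-normal(mu, sigma) rate distribution."""
    q1 = float(np.exp(mu - 0.6744897501960817 * sigma))
    q3 = float(np.exp(mu + 0.6744897501960817 * sigma))
    return q3 + 1.5 * (q3 - q1)


def gen_use_records(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate use-report records plus truth labels.

    Clean rates are log-normal draws truncated at 85% of the analytic
    fence, so that with the default contamination fractions the empirical
    fence of the contaminated sample always separates clean records from
    the injected contamination.  Outliers are drawn uniformly in
    [1.5, ``outlier_multiplier``] × fence; unit errors multiply an
    upper-half clean rate by ``unit_error_factor`` (mimicking a misplaced
    unit entry).  Counts are ``round(fraction × n_records)`` exactly.

    Returns ``(records, truth)`` where truth holds one label per record:
    ``clean``, ``outlier`` or ``unit_error``.
    """
    if cfg.n_records < 10:
        raise ValueError("n_records must be >= 10")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_records
    n_out = round(cfg.outlier_fraction * n)
    n_err = round(cfg.unit_error_fraction * n)
    n_clean = n - n_out - n_err
    fence = analytic_fence(cfg.rate_mu, cfg.rate_sigma)
    cap = 0.85 * fence

    def _clean_draws(size: int, lower: float = 0.0) -> np.ndarray:
        out = np.empty(0)
        while out.size < size:
            draw = rng.lognormal(cfg.rate_mu, cfg.rate_sigma, size=2 * size + 16)
            draw = draw[(draw <= cap) & (draw >= lower)]
            out = np.concatenate([out, draw])
        return out[:size]

    rates = _clean_draws(n_clean)
    outliers = rng.uniform(1.5 * fence, cfg.outlier_multiplier * fence, size=n_out)
    # unit-error victims come from the upper half of the clean distribution
    median = float(np.exp(cfg.rate_mu))
    errors = _clean_draws(n_err, lower=median) * cfg.unit_error_factor

    all_rates = np.concatenate([rates, outliers, errors])
    truth = np.array(
        ["clean"] * n_clean + ["outlier"] * n_out + ["unit_error"] * n_err
    )
    order = rng.permutation(n)
    all_rates, truth = all_rates[order], truth[order]

    crops = rng.choice(["almond", "grape", "citrus", "lettuce", "tomato"], size=n)
    products = rng.integers(1, 40, size=n)
    neat = rng.random(n) < cfg.neat_fraction
    records = pd.DataFrame(
        {
            "chemical_id": "sim-chem",
            "product_id": [f"prod-{i:03d}" for i in products],
            "crop": crops,
            "rate": all_rates,
            "unit": "kg/ha",
            "month": rng.integers(1, 13, size=n),
            "neat": neat,
        }
    )
    truth_df = pd.DataFrame({"truth": truth})
    return records, truth_df


def gen_residue_study(cfg: SimConfig) -> pd.DataFrame:
    """Generate a residue-study table in the CSV dialect the reader expects.

    Per matrix and day, ``replicates`` concentrations follow
    C0 · exp(-k · day) with multiplicative log-normal noise of the given
    CV; values below the matrix MDL are emitted censored (``<MDL``).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    sigma = np.sqrt(np.log1p(cfg.replicate_cv**2))
    rows = []
    for matrix, mp in cfg.matrix_params.items():
        for day in cfg.days:
            expect = mp["c0"] * np.exp(-mp["k"] * day)
            for rep in range(1, cfg.replicates + 1):
                noise = rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
                value = expect * noise
                censored = value < mp["mdl"]
                rows.append(
                    {
                        "matrix": matrix,
                        "day": day,
                        "replicate": rep,
                        "conc": f"<{mp['mdl']}" if censored else f"{value:.6g}",
                        "loq": mp["loq"],
                        "mdl": mp["mdl"],
                        "control": 0,
                        "invalid": 0,
                    }
                )
    return pd.DataFrame(rows)


def gen_dose_response(cfg: SimConfig) -> QuantalDoseResponse:
    """Generate quantal mortality from a log-logistic tolerance model.

    P(death | dose d) = 1 / (1 + (LD50 / d)^slope); deaths are binomial
    per dose group, plus an optional background-mortality control group.
    """
    doses = np.asarray(cfg.doses, float)
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be positive and ascending")
    rng = np.random.default_rng(cfg.seed + 2)
    p = 1.0 / (1.0 + (cfg.ld50 / doses) ** cfg.slope)
    dead = rng.binomial(cfg.n_per_dose, p)
    control_dead = rng.binomial(cfg.control_n, cfg.control_mortality)
    return QuantalDoseResponse(
        doses=tuple(doses),
        n_exposed=(cfg.n_per_dose,) * doses.size,
        n_dead=tuple(int(d) for d in dead),
        control=(cfg.control_n, int(control_dead)),
    )
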