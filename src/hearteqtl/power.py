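"""FDR-anchored eQTL power simulation.

For each minimum MAF level a population of eQTLs is simulated with log2
fold changes (effect per minor-allele copy) drawn uniformly over the
symmetric fold-change range, HWE genotypes at that MAF and Gaussian noise.
Every simulated eQTL is tested with the scan's additive model and the batch
is corrected with Benjamini-Hochberg at the target FDR.  For each grid
point X, power is the fraction of eQTLs with |log2 FC| > X whose null
hypothesis was rejected — a conditional power curve over the effect sizes
actually exceeding X.

The closed-form oracle is the noncentral t: the two-sided rejection
probability at level alpha for an additive effect beta at frequency q with
noise SD sigma is given by a noncentrality of
``beta * sqrt(n * 2 q (1-q)) / sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError
from .mapping import bh_stepup

#: minimum-MAF levels of the standard power analysis
DEFAULT_MAF_LEVELS = (0.05, 0.10, 0.15, 0.20, 0.30, 0.40)


@dataclass
class PowerGrid:
    """Configuration of the power simulation."""

    maf_levels: tuple = DEFAULT_MAF_LEVELS
    fold_changes: tuple = tuple(np.round(np.arange(0.0, 2.01, 0.25), 2))
    n: int = 129
    n_eqtls: int = 2000
    noise_sd: float = 1.0
    fdr: float = 0.05
    reps: int = 3
    seed: int = 0
    #: half-width of the simulated effect-size population; wider than the
    #: fold-change grid so the conditional set at the grid maximum is nonempty
    beta_max: float = 3.0

    def validate(self) -> None:
        if not self.maf_levels or not self.fold_changes:
            raise ValidationError("maf_levels and fold_changes must be nonempty")
        if not (0 < self.fdr < 1):
            raise ValidationError("fdr must lie in (0, 1)")
        if min(self.maf_levels) <= 0 or max(self.maf_levels) > 0.5:
            raise ValidationError("MAF levels must lie in (0, 0.5]")
        if self.n < 4 or self.n_eqtls < 1 or self.reps < 1:
            raise ValidationError("n, n_eqtls and reps must be positive (n >= 4)")
        if self.beta_max <= 0:
            raise ValidationError("beta_max must be > 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


def analytic_power(beta: float, maf: float, n: int, noise_sd: float, alpha: float) -> float:
    """Two-sided rejection probability of the additive test (noncentral t).

    With dosage variance ``2 maf (1-maf)`` the noncentrality parameter is
    ``beta * sqrt(n * 2 maf (1-maf)) / noise_sd``; at beta = 0 the power
    equals the level alpha.
    """
    if not (0 < maf <= 0.5):
        raise ValidationError("maf must lie in (0, 0.5]")
    if n < 3 or noise_sd <= 0 or not (0 < alpha < 1):
        raise ValidationError("invalid power parameters")
    df = n - 2
    ncp = beta * np.sqrt(n * 2 * maf * (1 - maf)) / noise_sd
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    # the tail opposite a large |ncp| underflows to NaN in scipy; it is
    # negligible there, so treat it as 0
    return float(np.nan_to_num(upper) + np.nan_to_num(lower))


def _simulate_rep(maf, grid: PowerGrid, rng):
    """One replicate: simulate, test, BH-correct; returns (|beta|, rejected)."""
    n, m = grid.n, grid.n_eqtls
    x_max = max(max(grid.fold_changes), grid.beta_max)
    betas = rng.uniform(-x_max, x_max, size=m)
    p = np.empty(m)
    for j in range(m):
        g = rng.binomial(2, maf, size=n).astype(float)
        y = betas[j] * g + rng.normal(0.0, grid.noise_sd, size=n)
        gc = g - g.mean()
        v = gc @ gc
        if v == 0:
            p[j] = 1.0
            continue
        b = (gc @ y) / v
        resid = y - y.mean() - b * gc
        df = n - 2
        se = np.sqrt(resid @ resid / df / v)
        tval = b / se if se > 0 else np.inf
        p[j] = max(2 * stats.t.sf(abs(tval), df), 1e-300)
    _, reject = bh_stepup(p, alpha=grid.fdr)
    return np.abs(betas), reject


def simulate_power(grid: PowerGrid) -> pd.DataFrame:
    """Power table over (maf, X): fraction of eQTLs with |log2 FC| > X rejected.

    Deterministic per ``grid.seed``; replicates are pooled before the
    conditional fractions are formed.
    """
    grid.validate()
    rows = []
    for maf in grid.maf_levels:
        rng = np.random.default_rng([int(grid.seed), 7, int(round(maf * 1000))])
        abs_beta = []
        rejected = []
        for _ in range(grid.reps):
            b, r = _simulate_rep(maf, grid, rng)
            abs_beta.append(b)
            rejected.append(r)
        abs_beta = np.concatenate(abs_beta)
        rejected = np.concatenate(rejected)
        for X in grid.fold_changes:
            sel = abs_beta > X
            power = float(rejected[sel].mean()) if sel.any() else np.nan
            rows.append(
                {"maf": maf, "X": X, "power": power, "n_eqtls": int(sel.sum()),
                 "reps": grid.reps, "seed": grid.seed}
            )
    return pd.DataFrame(rows)


def predicted_sensitivity(effects, n: int, noise_sd: float, alpha: float) -> float:
    """Mean analytic power over a set of (beta, maf) planted effects.

    Serves as the power-module prediction for the scan's sensitivity on a
    planted-effect cohort, at the per-test level alpha actually implied by
    the FDR correction.
    """
    powers = [analytic_power(b, q, n, noise_sd, alpha) for b, q in effects]
    return float(np.mean(powers))
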