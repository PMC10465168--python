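"""Strength-duration regression, excitability scoring and Morris screening.

Two-step regression: Lapicque's strength-duration law is fit to the total
averaged current at threshold, TAC(pd) = TAC0 / (1 - exp(-pd/tau)); the
intensity threshold is then regressed log-linearly on expression level and
the fitted TAC.  Excitability of (cell, opsin-location, ...) classes is
scored by mutually paired one-sided Wilcoxon signed-rank tests.  Global
sensitivity of the pipeline output to its uncertain inputs uses the
elementary-effects (Morris) screen with a radial design built on Sobol
points; all effects are measured per unit step in the unit hypercube so
heterogeneous factor types remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sstats
from scipy.stats import qmc

__all__ = [
    "RegressionFit",
    "EEFactorSpec",
    "EEResult",
    "lapicque_fit",
    "threshold_regression",
    "wilcoxon_excitability_scores",
    "ranked_relative_change",
    "elementary_effects",
]


@dataclass
class RegressionFit:
    """Parameters of the two-step strength-duration regression."""

    tac0: float            # rheobase-like asymptote (same units as TAC input)
    tau_tac: float         # chronaxie-like time constant, ms
    r2_tac: float          # adjusted R^2 of the Lapicque step
    a_g: float = np.nan    # log10 G_max coefficient
    a_pd: float = np.nan   # log10 TAC-hat coefficient
    c: float = np.nan      # intercept
    r2_tot: float = np.nan  # adjusted R^2 of the log-linear step

    def __post_init__(self) -> None:
        if self.tac0 <= 0 or self.tau_tac <= 0:
            raise ValueError("TAC0 and tau_TAC must be > 0")


def _adjusted_r2(y, yhat, n_params: int) -> float:
    y = np.asarray(y, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    n = len(y)
    if ss_tot == 0:
        return 1.0 if ss_res < 1e-30 else 0.0
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def lapicque_strength_duration(pd, tac0, tau):
    """TAC-hat(pd) = TAC0 / (1 - exp(-pd/tau))."""
    pd = np.asarray(pd, dtype=float)
    return tac0 / (1.0 - np.exp(-pd / tau))


def lapicque_fit(pd_values, tac_values):
    """Fit Lapicque's strength-duration law to (pd, TAC) pairs.

    Returns ``(tac0, tau_tac, adjusted_r2)``.  Requires at least three
    pairs with pd > 0 and positive TAC.
    """
    pd_values = np.asarray(pd_values, dtype=float)
    tac_values = np.asarray(tac_values, dtype=float)
    ok = np.isfinite(pd_values) & np.isfinite(tac_values)
    pd_values, tac_values = pd_values[ok], tac_values[ok]
    if len(pd_values) < 3:
        raise ValueError("need at least 3 (pd, TAC) pairs")
    if np.any(pd_values <= 0) or np.any(tac_values <= 0):
        raise ValueError("pd and TAC must be positive")
    tac0_guess = float(tac_values[np.argmax(pd_values)])
    tau_guess = float(np.median(pd_values))

    # fit in log space: TAC spans decades across pulse durations, and the
    # multiplicative measurement error makes log residuals homoscedastic
    def log_model(pd, tac0, tau):
        return np.log(lapicque_strength_duration(pd, tac0, tau))

    try:
        popt, _ = optimize.curve_fit(
            log_model, pd_values, np.log(tac_values),
            p0=[tac0_guess, tau_guess],
            bounds=([1e-300, 1e-6], [np.inf, np.inf]), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            "Lapicque fit failed to converge "
            f"(initial guess TAC0={tac0_guess:.3g}, tau={tau_guess:.3g})"
        ) from exc
    yhat = lapicque_strength_duration(pd_values, *popt)
    return float(popt[0]), float(popt[1]), _adjusted_r2(tac_values, yhat, 2)


def threshold_regression(g_max_values, tac_hat_values, i_th_values):
    """OLS of log10 I_th on log10 G_max and log10 TAC-hat.

    Returns ``(a_g, a_pd, c, adjusted_r2)``; the adjusted R^2 uses an
    n - 3 denominator (two slopes plus intercept).  Rank deficiency (e.g.
    a single G_max level) raises.
    """
    g = np.asarray(g_max_values, dtype=float)
    tac = np.asarray(tac_hat_values, dtype=float)
    ith = np.asarray(i_th_values, dtype=float)
    ok = np.isfinite(g) & np.isfinite(tac) & np.isfinite(ith)
    g, tac, ith = g[ok], tac[ok], ith[ok]
    if np.any(g <= 0) or np.any(tac <= 0) or np.any(ith <= 0):
        raise ValueError("inputs must be positive")
    if len(g) < 4:
        raise ValueError("need at least 4 points for the 3-parameter fit")
    X = np.column_stack([np.log10(g), np.log10(tac), np.ones(len(g))])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("design matrix is rank deficient "
                         "(collinear or single-level predictors)")
    y = np.log10(ith)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    return (float(beta[0]), float(beta[1]), float(beta[2]),
            _adjusted_r2(y, yhat, 2))


def fit_two_step(pd_values, g_max_values, tac_values, i_th_values) -> RegressionFit:
    """Full two-step pipeline on pooled (pd, G_max, TAC, I_th) samples."""
    pd_values = np.asarray(pd_values, dtype=float)
    tac0, tau, r2_tac = lapicque_fit(pd_values, np.asarray(tac_values, float))
    tac_hat = lapicque_strength_duration(pd_values, tac0, tau)
    a_g, a_pd, c, r2_tot = threshold_regression(g_max_values, tac_hat,
                                                i_th_values)
    return RegressionFit(tac0=tac0, tau_tac=tau, r2_tac=r2_tac,
                         a_g=a_g, a_pd=a_pd, c=c, r2_tot=r2_tot)


# ---------------------------------------------------------------------------
# Wilcoxon excitability scoring

_SCORE_TIERS = ((0.001, 1.0), (0.01, 0.1), (0.05, 0.01))


def wilcoxon_one_sided(greater, lesser) -> float:
    """p-value of the paired one-sided signed-rank test (H1: greater > lesser).

    Zero differences are discarded (the standard zero-discard convention);
    scipy uses exact enumeration for small samples without ties and the
    tie-corrected normal approximation otherwise.
    """
    greater = np.asarray(greater, dtype=float)
    lesser = np.asarray(lesser, dtype=float)
    if greater.shape != lesser.shape:
        raise ValueError("paired samples must have equal length")
    diff = greater - lesser
    if np.all(diff == 0):
        return 1.0
    return float(sstats.wilcoxon(greater, lesser, alternative="greater",
                                 zero_method="wilcox").pvalue)


def wilcoxon_excitability_scores(class_vectors: dict, larger_is_better: bool = True):
    """Score each class by how often it significantly beats the others.

    For every ordered pair a one-sided paired Wilcoxon signed-rank test is
    run; the winning class collects 1, 0.1 or 0.01 for p < 0.001, 0.01 and
    0.05 respectively.  With n classes the maximum score is n - 1.  Returns
    ``(scores, pvalues)`` where ``pvalues[(a, b)]`` tests a beats b.
    """
    names = list(class_vectors)
    lengths = {len(np.asarray(v)) for v in class_vectors.values()}
    if len(lengths) != 1:
        raise ValueError("all class vectors must be paired (equal length)")
    scores = {k: 0.0 for k in names}
    pvals = {}
    for a in names:
        for b in names:
            if a == b:
                continue
            if larger_is_better:
                p = wilcoxon_one_sided(class_vectors[a], class_vectors[b])
            else:
                p = wilcoxon_one_sided(class_vectors[b], class_vectors[a])
            pvals[(a, b)] = p
            for cutoff, pts in _SCORE_TIERS:
                if p < cutoff:
                    scores[a] += pts
                    break
    return scores, pvals


def pvalue_matrix(pvals: dict):
    """Square p-value table (rows beat columns), classes sorted by wins."""
    import pandas as pd

    names = sorted({a for a, _ in pvals} | {b for _, b in pvals})
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), p in pvals.items():
        mat.loc[a, b] = p
    return mat


def ranked_relative_change(values):
    """Per-step relative changes along a ranking and their median.

    ``values`` must be ordered from worst to best rank; the k-th change is
    (v[k+1] - v[k]) / v[k].  Returns ``(changes, median)``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 ranked values")
    changes = np.diff(values) / values[:-1]
    return changes, float(np.median(changes))


def average_of_medians(sequences) -> float:
    """Mean of the per-sequence median relative changes."""
    meds = [ranked_relative_change(seq)[1] for seq in sequences]
    return float(np.mean(meds))


# ---------------------------------------------------------------------------
# elementary effects (Morris screening, radial Sobol design)

@dataclass(frozen=True)
class EEFactorSpec:
    """One uncertain factor of the sensitivity screen.

    kind 'normal': params (mean, cv), truncated at +-4 standard deviations;
    kind 'uniform': params (low, high);
    kind 'discrete': params is the tuple of class labels (uniform).
    """

    name: str
    kind: str
    params: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "uniform", "discrete"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind == "normal":
            mean, cv = self.params
            if cv <= 0:
                raise ValueError("coefficient of variation must be > 0")
        if self.kind == "discrete" and len(self.params) == 0:
            raise ValueError("discrete factor needs at least one class")

    @property
    def n_classes(self) -> int:
        return len(self.params) if self.kind == "discrete" else 0

    def transform(self, u: float):
        """Map a unit-hypercube coordinate through the inverse CDF."""
        if self.kind == "normal":
            mean, cv = self.params
            sd = abs(mean) * cv
            a, b = -4.0, 4.0  # truncation in standard units
            return mean + sd * sstats.truncnorm.ppf(u, a, b)
        if self.kind == "uniform":
            low, high = self.params
            return low + (high - low) * u
        idx = min(int(u * len(self.params)), len(self.params) - 1)
        return self.params[idx]


@dataclass
class EEResult:
    """mu* (mean |EE|), sigma (SD of EEs) and rank per factor."""

    factors: list
    mu_star: np.ndarray
    sigma: np.ndarray
    mu: np.ndarray
    effects: np.ndarray      # (r, k) raw elementary effects
    rank: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(-self.mu_star, kind="stable")
        self.rank = np.empty(len(self.factors), dtype=int)
        self.rank[order] = np.arange(1, len(self.factors) + 1)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "factor": self.factors, "mu_star": self.mu_star,
            "sigma": self.sigma, "mu": self.mu, "rank": self.rank})


def _discrete_step(spec: EEFactorSpec, u_base: float, u_aux: float):
    """Auxiliary coordinate for a discrete factor, forced to a new class."""
    m = spec.n_classes
    if m < 2:
        return u_base
    c_base = min(int(u_base * m), m - 1)
    c_aux = min(int(u_aux * m), m - 1)
    if c_aux == c_base:
        c_aux = (c_base + 1) % m
    return (c_aux + 0.5) / m


def elementary_effects(model, specs, r: int = 16, seed: int = 0,
                       skip: int = 0) -> EEResult:
    """Morris elementary-effects screen with a radial Sobol design.

    For each of ``r`` repetitions a Sobol point in [0,1]^{2k} provides a
    base point ``a`` (first k coordinates) and auxiliary coordinates ``b``
    (last k).  The j-th elementary effect of repetition i is

        EE_ij = (f(a with a_j -> b_j) - f(a)) / (b_j - a_j)

    with the denominator measured in the unit hypercube, so effects of
    mixed-type factors (physical, angular, categorical) share a scale.
    For discrete factors the auxiliary coordinate is forced onto a
    different class.  Deterministic given ``seed``.
    """
    specs = list(specs)
    k = len(specs)
    if r < 2:
        raise ValueError("r must be >= 2")
    sob = qmc.Sobol(d=2 * k, scramble=True, rng=np.random.default_rng(seed))
    if skip:
        sob.fast_forward(skip)
    pts = sob.random(r)
    effects = np.empty((r, k))
    for i in range(r):
        a = pts[i, :k].copy()
        b = pts[i, k:].copy()
        for j, spec in enumerate(specs):
            if spec.kind == "discrete":
                b[j] = _discrete_step(spec, a[j], b[j])
            elif abs(b[j] - a[j]) < 1e-9:
                b[j] = (a[j] + 0.5) % 1.0
        base_x = [spec.transform(a[j]) for j, spec in enumerate(specs)]
        try:
            f_base = float(model(base_x))
        except Exception as exc:
            raise RuntimeError(f"model failed at base point {base_x}") from exc
        for j, spec in enumerate(specs):
            x = list(base_x)
            x[j] = spec.transform(b[j])
            try:
                f_pert = float(model(x))
            except Exception as exc:
                raise RuntimeError(f"model failed at point {x}") from exc
            effects[i, j] = (f_pert - f_base) / (b[j] - a[j])
    mu = effects.mean(axis=0)
    mu_star = np.abs(effects).mean(axis=0)
    sigma = effects.std(axis=0, ddof=1)
    return EEResult(factors=[s.name for s in specs], mu_star=mu_star,
                    sigma=sigma, mu=mu, effects=effects)
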