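"""Quantile-regression recovery estimation for accelerometer metrics.

After capture and release, movement metrics such as VeDBA and jerk are
shifted away from their baseline and relax back as the animal recovers.
The model fitted here is, for a chosen quantile level tau,

    log Y_tau(t) = beta_ind + alpha_g * z,      z = 1 / (t + 1),

with one free offset ``beta_ind`` per animal (its baseline on the log
scale) and one slope ``alpha_g`` per group of animals (the tagging effect;
a categorical covariate such as handling-time class enters the model as
one slope per level).  On the original scale the model is a multiplicative
perturbation ``exp(alpha * z)`` of the baseline that decays to 1 as t grows.

The return time for a tolerance ``delta`` in (0, 1) is the time at which
the multiplicative effect has shrunk to within a factor ``delta`` of
baseline, i.e. the solution of ``exp(alpha z) = delta``:

    t_R = max(0, |alpha| / |ln delta| - 1).

|alpha| is used so that suppressed (alpha < 0) and elevated (alpha > 0)
responses are treated symmetrically.

Fitting minimizes the pinball (check) loss.  Two interchangeable solvers
are provided: an exact linear-programming route (HiGHS) with a
deterministic tie-break to the smallest coefficient sum, and a structured
iteratively-reweighted least-squares route that exploits the
animal-offsets-plus-group-slope design and scales to hundreds of
thousands of observations.  Confidence intervals and slope tests use a
cluster bootstrap with the animal as resampling unit, which respects
within-animal serial dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, sparse, stats

from .preprocess import MetricSeries

__all__ = [
    "QRDesign",
    "QRFit",
    "RecoveryEstimate",
    "SlopeTest",
    "pinball_loss",
    "fit_quantile_model",
    "recovery_time",
    "recovery_curve",
    "bootstrap_ci",
    "compare_slopes",
]


def pinball_loss(u: np.ndarray, tau: float) -> np.ndarray:
    """Check loss rho_tau(u) = u * (tau - 1{u < 0}), elementwise."""
    u = np.asarray(u, dtype=float)
    return u * (tau - (u < 0))


@dataclass
class QRDesign:
    """Observations for the quantile recovery model.

    ``animal``/``group`` are per-observation labels; ``t`` is hours since
    release; ``y`` the strictly positive metric value (log taken
    internally); ``tau`` the quantile level.
    """

    animal: np.ndarray
    group: np.ndarray
    t: np.ndarray
    y: np.ndarray
    tau: float
    response_name: str = "metric"

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.t.size
        if not (self.animal.size == self.group.size == self.y.size == n and n > 0):
            raise ValueError("animal, group, t, y must be equal-length and non-empty")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie strictly inside (0, 1)")
        if np.any(self.y <= 0) or not np.all(np.isfinite(self.y)):
            raise ValueError("responses must be finite and strictly positive")
        if np.any(self.t < 0):
            raise ValueError("times must be nonnegative (hours since release)")

    @property
    def z(self) -> np.ndarray:
        """Inverse-time covariate z = 1/(t+1) in (0, 1]."""
        return 1.0 / (self.t + 1.0)

    @property
    def groups(self) -> list:
        return sorted(set(self.group.tolist()))

    @classmethod
    def from_series(
        cls,
        series: list[MetricSeries],
        group_of: dict[str, str],
        tau: float,
    ) -> "QRDesign":
        """Stack per-animal metric series into one design."""
        if not series:
            raise ValueError("no metric series supplied")
        animal = np.concatenate([[m.animal_id] * m.time_h.size for m in series])
        group = np.array([group_of[a] for a in animal], dtype=object)
        t = np.concatenate([m.time_h for m in series])
        y = np.concatenate([m.value for m in series])
        keep = y > 0  # zero metric values carry no log-scale information
        return cls(animal[keep], group[keep], t[keep], y[keep], tau,
                   response_name=series[0].metric_name)

    def subset(self, mask: np.ndarray) -> "QRDesign":
        return QRDesign(
            self.animal[mask], self.group[mask], self.t[mask], self.y[mask],
            self.tau, self.response_name,
        )


@dataclass
class QRFit:
    """Fitted quantile recovery model."""

    tau: float
    beta_ind: dict
    alpha: dict
    loss: float
    n_obs: int
    method: str
    response_name: str = "metric"

    def predict_log(self, animal, group, t: np.ndarray) -> np.ndarray:
        z = 1.0 / (np.asarray(t, dtype=float) + 1.0)
        return self.beta_ind[animal] + self.alpha[group] * z


@dataclass
class RecoveryEstimate:
    """Return time at a given tolerance, optionally with a bootstrap CI."""

    tau: float
    group: str
    delta: float
    t_r: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    method: str = "closed_form"
    n_boot: int | None = None
    seed: int | None = None


@dataclass
class SlopeTest:
    """Wald-type comparison of two fitted decay slopes."""

    contrast: str
    statistic: float
    p_value: float
    difference: float
    se: float
    n_boot: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# solvers


def _validate_group(z: np.ndarray, animal_codes: np.ndarray, include_decay: bool) -> None:
    if include_decay and np.unique(z).size < 2:
        raise ValueError("degenerate design: a single distinct time value")
    for a in np.unique(animal_codes):
        if np.unique(z[animal_codes == a]).size < 2 and include_decay:
            raise ValueError("each animal needs at least two distinct time values")


def _fit_lp(
    ly: np.ndarray, z: np.ndarray, animal_codes: np.ndarray, n_animals: int,
    tau: float, include_decay: bool,
) -> tuple[np.ndarray, float]:
    """Exact pinball minimization as a linear program.

    Variables: [beta+ (A), beta- (A), alpha+, alpha-, u+ (n), u- (n)] with
    X beta + u+ - u- = ly.  A secondary LP breaks ties among exact minimizers
    toward the smallest coefficient sum (lower endpoint in one dimension).
    """
    n = ly.size
    p = n_animals + (1 if include_decay else 0)
    cols = [sparse.csc_matrix((np.ones(n), (np.arange(n), animal_codes)), shape=(n, n_animals))]
    if include_decay:
        cols.append(sparse.csc_matrix(z.reshape(-1, 1)))
    X = sparse.hstack(cols, format="csc")
    A_eq = sparse.hstack([X, -X, sparse.eye(n), -sparse.eye(n)], format="csc")
    c = np.concatenate([np.zeros(2 * p), np.full(n, tau), np.full(n, 1 - tau)])
    res = optimize.linprog(c, A_eq=A_eq, b_eq=ly, method="highs")
    if not res.success:  # pragma: no cover - LP on this design is always feasible
        raise RuntimeError(f"quantile LP failed: {res.message}")
    loss = float(res.fun)
    # tie-break: among solutions attaining the optimal loss, minimize the
    # coefficient sum (beta+ + beta- penalized, so also sparsest signs)
    c2 = np.concatenate([np.ones(p), np.zeros(p), np.zeros(2 * n)])
    A_ub = sparse.csr_matrix(c.reshape(1, -1))
    res2 = optimize.linprog(
        c2, A_ub=A_ub, b_ub=[loss + 1e-9 * max(1.0, abs(loss)) + 1e-12],
        A_eq=A_eq, b_eq=ly, method="highs",
    )
    chosen = res2 if res2.success else res
    coef = chosen.x[:p] - chosen.x[p : 2 * p]
    xb = coef[animal_codes] + (coef[-1] * z if include_decay else 0.0)
    return coef, float(np.sum(pinball_loss(ly - xb, tau)))


def _fit_irls(
    ly: np.ndarray, z: np.ndarray, animal_codes: np.ndarray, n_animals: int,
    tau: float, include_decay: bool, tol: float = 1e-8, max_iter: int = 200,
    eps: float = 1e-6, beta0: np.ndarray | None = None, alpha0: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Iteratively reweighted least squares on the arrowhead design.

    The normal equations for [per-animal offsets | one slope] have
    diagonal-plus-border structure, so each iteration costs a handful of
    bincounts over the observations.  ``beta0``/``alpha0`` warm-start the
    iteration (used heavily by the bootstrap).
    """
    if np.any(np.diff(animal_codes) < 0):  # group observations contiguously
        order = np.argsort(animal_codes, kind="stable")
        ly, z, animal_codes = ly[order], z[order], animal_codes[order]
    counts = np.bincount(animal_codes, minlength=n_animals)
    bounds = np.concatenate([[0], np.cumsum(counts)[:-1]])
    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
    else:
        beta = np.array(
            [np.quantile(ly[b : b + c], tau) for b, c in zip(bounds, counts)]
        )
    alpha = alpha0
    for _ in range(max_iter):
        r = ly - np.repeat(beta, counts) - (alpha * z if include_decay else 0.0)
        w = np.where(r >= 0, tau, 1 - tau) / np.maximum(np.abs(r), eps)
        s = np.add.reduceat(w, bounds)
        rw = np.add.reduceat(w * ly, bounds)
        if include_decay:
            wz = w * z
            cz = np.add.reduceat(wz, bounds)
            denom = float(wz @ z) - np.sum(cz * cz / s)
            new_alpha = (float(wz @ ly) - np.sum(cz * rw / s)) / denom if denom > 0 else 0.0
            new_beta = (rw - new_alpha * cz) / s
        else:
            new_alpha = 0.0
            new_beta = rw / s
        shift = max(
            float(np.max(np.abs(new_beta - beta))), abs(new_alpha - alpha)
        )
        beta, alpha = new_beta, new_alpha
        if shift < tol:
            break
    coef = np.concatenate([beta, [alpha]]) if include_decay else beta
    r = ly - np.repeat(beta, counts) - (alpha * z if include_decay else 0.0)
    return coef, float(np.sum(pinball_loss(r, tau)))


def fit_quantile_model(
    design: QRDesign,
    method: str = "auto",
    include_decay: bool = True,
    exact_max_n: int = 2000,
) -> QRFit:
    """Fit per-animal offsets and per-group decay slopes at ``design.tau``.

    Because each animal belongs to exactly one group, the pinball objective
    separates over groups and each group is fitted independently.
    ``method`` is ``'exact'`` (LP), ``'irls'`` or ``'auto'`` (exact up to
    ``exact_max_n`` observations per group, IRLS beyond).  Both routes are
    deterministic given the data.
    """
    if method not in ("auto", "exact", "irls"):
        raise ValueError("method must be 'auto', 'exact' or 'irls'")
    beta_ind: dict = {}
    alpha: dict = {}
    total_loss = 0.0
    used = []
    for g in design.groups:
        mask = design.group == g
        ly = np.log(design.y[mask])
        z = design.z[mask]
        animals, codes = np.unique(design.animal[mask], return_inverse=True)
        _validate_group(z, codes, include_decay)
        m = "exact" if method == "exact" or (method == "auto" and ly.size <= exact_max_n) else "irls"
        solver = _fit_lp if m == "exact" else _fit_irls
        coef, loss = solver(ly, z, codes, animals.size, design.tau, include_decay)
        for a, b in zip(animals, coef[: animals.size]):
            beta_ind[a] = float(b)
        alpha[g] = float(coef[-1]) if include_decay else 0.0
        total_loss += loss
        used.append(m)
    return QRFit(
        tau=design.tau,
        beta_ind=beta_ind,
        alpha=alpha,
        loss=total_loss,
        n_obs=design.y.size,
        method="+".join(sorted(set(used))),
        response_name=design.response_name,
    )


# ---------------------------------------------------------------------------
# return times


def _t_r_from_alpha(alpha: float, delta: float) -> float:
    return max(0.0, abs(alpha) / abs(np.log(delta)) - 1.0)


def recovery_time(fit: QRFit, group: str, delta: float = 0.25) -> RecoveryEstimate:
    """Closed-form return time: t_R = max(0, |alpha| / |ln delta| - 1).

    This is the root in t of exp(alpha z) = delta with z = 1/(t+1); it is 0
    whenever |alpha| <= |ln delta| (the effect is already within tolerance
    at release).
    """
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie in (0, 1)")
    return RecoveryEstimate(fit.tau, group, delta, _t_r_from_alpha(fit.alpha[group], delta))


def recovery_curve(
    fit: QRFit, group: str, delta_grid: np.ndarray, cap_h: float | None = None
) -> list[RecoveryEstimate]:
    """Return times over a grid of tolerances (nonincreasing in delta).

    ``cap_h`` caps the reported time (e.g. at the record length) for
    delta -> 1 where the closed form diverges for nonzero slopes.
    """
    out = []
    for d in np.asarray(delta_grid, dtype=float):
        est = recovery_time(fit, group, d)
        if cap_h is not None:
            est = replace(est, t_r=min(est.t_r, cap_h))
        out.append(est)
    return out


# ---------------------------------------------------------------------------
# bootstrap inference


@dataclass
class _GroupArrays:
    """Numeric view of one group's data plus its full-sample solution.

    Avoids rebuilding object-dtype designs inside bootstrap loops; the
    full-sample (beta, alpha) warm-starts every replicate refit.
    """

    ly: np.ndarray
    z: np.ndarray
    codes: np.ndarray
    n_animals: int
    idx_by_animal: list
    tau: float
    solver: str
    beta: np.ndarray
    alpha: float


def _prepare_group(design: QRDesign, group: str, method: str) -> _GroupArrays:
    mask = design.group == group
    if not mask.any():
        raise ValueError(f"group {group!r} not present in the design")
    ly = np.log(design.y[mask])
    z = design.z[mask]
    animals, codes = np.unique(design.animal[mask], return_inverse=True)
    _validate_group(z, codes, True)
    solver = (
        "exact" if method == "exact" or (method == "auto" and ly.size <= 2000) else "irls"
    )
    if solver == "exact":
        coef, _ = _fit_lp(ly, z, codes, animals.size, design.tau, True)
    else:
        coef, _ = _fit_irls(ly, z, codes, animals.size, design.tau, True)
    return _GroupArrays(
        ly=ly, z=z, codes=codes, n_animals=animals.size,
        idx_by_animal=[np.flatnonzero(codes == a) for a in range(animals.size)],
        tau=design.tau, solver=solver, beta=coef[:-1], alpha=float(coef[-1]),
    )


def _refit_alpha(ga: _GroupArrays, picks: np.ndarray) -> float:
    """Slope refit on a cluster resample given animal picks (warm-started)."""
    idx = np.concatenate([ga.idx_by_animal[p] for p in picks])
    codes = np.repeat(
        np.arange(picks.size), [ga.idx_by_animal[p].size for p in picks]
    )
    if ga.solver == "exact":
        coef, _ = _fit_lp(ga.ly[idx], ga.z[idx], codes, picks.size, ga.tau, True)
    else:
        coef, _ = _fit_irls(
            ga.ly[idx], ga.z[idx], codes, picks.size, ga.tau, True,
            tol=1e-6, beta0=ga.beta[picks], alpha0=ga.alpha,
        )
    return float(coef[-1])


def _resample_blocks(design: QRDesign, group: str, rng: np.random.Generator,
                     block_h: float = 5.0) -> QRDesign:
    """Within-animal disjoint time-block bootstrap (few-animal fallback)."""
    mask = design.group == group
    keep_parts = []
    for a in np.unique(design.animal[mask]):
        idx = np.flatnonzero(design.animal == a)
        blocks = np.floor(design.t[idx] / block_h).astype(np.int64)
        uniq = np.unique(blocks)
        picks = rng.choice(uniq, size=uniq.size, replace=True)
        keep_parts.extend(idx[blocks == b] for b in picks)
    idx = np.concatenate(keep_parts)
    return QRDesign(
        design.animal[idx], design.group[idx], design.t[idx], design.y[idx],
        design.tau, design.response_name,
    )


def _boot_alphas(
    design: QRDesign, group: str, n_boot: int, rng: np.random.Generator,
    method: str,
) -> np.ndarray:
    ga = _prepare_group(design, group, method)
    if ga.n_animals >= 3:
        out = np.empty(n_boot)
        for b in range(n_boot):
            out[b] = _refit_alpha(ga, rng.integers(0, ga.n_animals, ga.n_animals))
        return out
    warnings.warn(
        f"group {group!r} has {ga.n_animals} animals; falling back to "
        "within-animal time-block bootstrap", stacklevel=3,
    )
    out = np.empty(n_boot)
    for b in range(n_boot):
        resampled = _resample_blocks(design, group, rng)
        out[b] = fit_quantile_model(resampled, method=method).alpha[group]
    return out


def bootstrap_ci(
    design: QRDesign,
    fit: QRFit,
    group: str,
    delta: float = 0.25,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "auto",
    level: float = 0.95,
    interval: str = "expanded",
) -> RecoveryEstimate:
    """Cluster-bootstrap interval for the return time.

    The resampling unit is the animal; groups with fewer than three
    animals fall back to within-animal time blocks.  With the typical
    handful of animals per group the plain percentile interval is too
    narrow (the bootstrap spread is estimated from few clusters), so the
    default ``interval='expanded'`` widens the quantile levels by the
    t-versus-normal ratio for G clusters (Hesterberg's expanded
    percentile); ``interval='percentile'`` gives the unadjusted band.
    Deterministic given ``seed``.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    if interval not in ("expanded", "percentile"):
        raise ValueError("interval must be 'expanded' or 'percentile'")
    rng = np.random.default_rng(seed)
    alphas = _boot_alphas(design, group, n_boot, rng, method)
    t_rs = np.array([_t_r_from_alpha(a, delta) for a in alphas])
    a_level = (1 - level) / 2
    if interval == "expanded":
        g = np.unique(design.animal[design.group == group]).size
        if g >= 3:
            z_adj = np.sqrt(g / (g - 1)) * stats.t.ppf(1 - a_level, g - 1)
            a_level = float(stats.norm.cdf(-z_adj))
    lo, hi = np.quantile(t_rs, [a_level, 1 - a_level])
    point = recovery_time(fit, group, delta)
    return replace(
        point,
        ci_lower=float(min(lo, point.t_r)),
        ci_upper=float(max(hi, point.t_r)),
        method=f"cluster_bootstrap_{interval}",
        n_boot=n_boot,
        seed=seed,
    )


def compare_slopes(
    design_a: QRDesign,
    design_b: QRDesign,
    group_a: str,
    group_b: str,
    n_boot: int = 200,
    seed: int = 0,
    method: str = "auto",
    contrast: str | None = None,
) -> SlopeTest:
    """Wald-type test of slope equality via the cluster bootstrap.

    Supports group-vs-group contrasts (independent animal sets, independent
    resampling) and quantile-vs-quantile contrasts on the same animals
    (``design_a``/``design_b`` differing only in tau; resampling is then
    paired so the difference reflects the quantile contrast, not animal
    draw).  The statistic is the slope difference over its bootstrap
    standard error, with a two-sided normal p-value.
    """
    fit_a = fit_quantile_model(design_a.subset(design_a.group == group_a), method=method)
    fit_b = fit_quantile_model(design_b.subset(design_b.group == group_b), method=method)
    diff = fit_a.alpha[group_a] - fit_b.alpha[group_b]
    animals_a = set(np.unique(design_a.animal[design_a.group == group_a]).tolist())
    animals_b = set(np.unique(design_b.animal[design_b.group == group_b]).tolist())
    paired = animals_a == animals_b and group_a == group_b
    rng = np.random.default_rng(seed)
    if paired:
        ga = _prepare_group(design_a, group_a, method)
        gb = _prepare_group(design_b, group_b, method)
        diffs = np.empty(n_boot)
        for b in range(n_boot):
            picks = rng.integers(0, ga.n_animals, ga.n_animals)  # shared draw
            diffs[b] = _refit_alpha(ga, picks) - _refit_alpha(gb, picks)
    else:
        aa = _boot_alphas(design_a, group_a, n_boot, rng, method)
        bb = _boot_alphas(design_b, group_b, n_boot, rng, method)
        diffs = aa - bb
    se = float(np.std(diffs, ddof=1))
    name = contrast or (
        f"alpha[{group_a}, tau={design_a.tau}] - alpha[{group_b}, tau={design_b.tau}]"
    )
    if diff == 0.0:
        return SlopeTest(name, 0.0, 1.0, 0.0, se, n_boot)
    if se == 0.0:
        warnings.warn("degenerate bootstrap variance; p-value undefined", stacklevel=2)
        return SlopeTest(name, np.inf, np.nan, diff, 0.0, n_boot, degenerate=True)
    stat = diff / se
    p = 2.0 * stats.norm.sf(abs(stat))
    return SlopeTest(name, float(stat), float(p), float(diff), se, n_boot)
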