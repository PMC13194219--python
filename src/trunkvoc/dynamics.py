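"""Temporal emission dynamics and rank-based group comparisons.

Daily duplicate measurements are aggregated to mean ± SEM series.  Single-
peak rise-and-decay dynamics are modeled with the four-parameter 'Extreme'
peak function

    y(x) = y0 + A · exp(−e^(−z) − z + 1),    z = (x − xc) / w

whose maximum y0 + A is attained exactly at x = xc; y0 is the emission
offset, A the amplitude, xc the peak day and w the peak width in days.

Group differences in emission rates use the tie-corrected Kruskal–Wallis
rank-sum test followed by Dunn's post-hoc z test on mean ranks (implemented
here; optionally Holm-adjusted).  Correlated emission dynamics are grouped
by single linkage over pairwise Kendall τ-b.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats

__all__ = [
    "ExtremeParams",
    "FitResult",
    "TauGrouping",
    "daily_aggregate",
    "eval_extreme",
    "fit_extreme",
    "kendall_tau",
    "tau_group",
    "kruskal_wallis",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class ExtremeParams:
    """Parameters of the 'Extreme' peak function."""

    y0: float
    A: float
    xc: float
    w: float

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError("peak width w must be > 0")


@dataclass
class FitResult:
    params: ExtremeParams | None
    adj_r2: float
    converged: bool
    n_points: int
    message: str = ""


@dataclass
class TauGrouping:
    compounds: list[str]
    tau: pd.DataFrame
    p: pd.DataFrame
    groups: list[set[str]]


def daily_aggregate(points: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicate observations to per-day mean ± SEM.

    ``points`` needs columns ``day`` and ``rate``.  SEM is the sample
    standard deviation over the k replicates divided by √k; undefined (NaN)
    for a single replicate.  For duplicate determinations this equals
    |a − b| / 2.
    """
    def _sem(x):
        return x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else float("nan")

    out = points.groupby("day")["rate"].agg(mean="mean", sem=_sem, k="size")
    return out.reset_index()


def eval_extreme(params: ExtremeParams, x) -> np.ndarray | float:
    """Evaluate the 'Extreme' peak function at day(s) *x*."""
    z = (np.asarray(x, dtype=float) - params.xc) / params.w
    # far left of the peak e^(−z) overflows; the model value is exactly 0 there
    with np.errstate(over="ignore"):
        y = params.y0 + params.A * np.exp(-np.exp(-z) - z + 1.0)
    return float(y) if np.isscalar(x) else y


def _extreme_fn(x, y0, A, xc, w):
    z = (x - xc) / w
    with np.errstate(over="ignore"):
        return y0 + A * np.exp(-np.exp(-z) - z + 1.0)


def _initial_guess(day: np.ndarray, y: np.ndarray) -> ExtremeParams:
    y0 = float(y.min())
    A = float(y.max() - y.min())
    xc = float(day[int(np.argmax(y))])
    half = y0 + A / 2.0
    w = max(1.0, float(np.sum(y > half)) / 2.0)
    return ExtremeParams(y0=y0, A=A, xc=xc, w=w)


def fit_extreme(
    series: pd.DataFrame,
    init: ExtremeParams | None = None,
    seed: int = 0,
    n_restarts: int = 3,
) -> FitResult:
    """Nonlinear least-squares fit of the 'Extreme' function to a daily series.

    ``series`` needs columns ``day`` and ``mean``.  Initialization follows a
    single-peak heuristic (peak at the series maximum, width from the number
    of above-half-maximum days); on non-convergence up to ``n_restarts``
    jittered restarts are tried with a fixed seed.  Adjusted R² uses
    p = 4 parameters.  A flat series is degenerate and rejected.
    """
    day = np.asarray(series["day"], dtype=float)
    y = np.asarray(series["mean"], dtype=float)
    if len(day) < 5:
        raise ValueError("need at least 5 points to fit a 4-parameter peak")
    if np.ptp(y) == 0:
        raise ValueError("series has no variance; nothing to fit")

    guess = init or _initial_guess(day, y)
    rng = np.random.default_rng(seed)
    model = Model(_extreme_fn)
    n = len(y)
    sst = float(np.sum((y - y.mean()) ** 2))

    attempts = [guess]
    for _ in range(n_restarts):
        attempts.append(
            ExtremeParams(
                y0=guess.y0 * (1 + 0.2 * rng.standard_normal()),
                A=guess.A * abs(1 + 0.3 * rng.standard_normal()),
                xc=guess.xc + guess.w * rng.standard_normal(),
                w=max(1.0, guess.w * abs(1 + 0.3 * rng.standard_normal())),
            )
        )

    best = None
    for att in attempts:
        pars = model.make_params(y0=att.y0, A=att.A, xc=att.xc, w=att.w)
        pars["w"].set(min=1e-6)
        try:
            res = model.fit(y, pars, x=day)
        except Exception:  # numeric failure in one start is not fatal
            continue
        if not res.success:
            continue
        ssr = float(np.sum(res.residual**2))
        if best is None or ssr < best[0]:
            best = (ssr, res)

    if best is None:
        return FitResult(
            params=None, adj_r2=float("nan"), converged=False,
            n_points=n, message="no start converged",
        )
    ssr, res = best
    r2 = 1.0 - ssr / sst
    p = 4
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else float("nan")
    fitted = ExtremeParams(
        y0=float(res.params["y0"].value),
        A=float(res.params["A"].value),
        xc=float(res.params["xc"].value),
        w=float(res.params["w"].value),
    )
    return FitResult(params=fitted, adj_r2=adj_r2, converged=True, n_points=n)


def kendall_tau(x: pd.Series, y: pd.Series) -> tuple[float, float]:
    """Kendall τ-b (tie-corrected) with a two-sided p-value.

    Series are aligned on their index (sampling day); at least 3 shared
    days are required.
    """
    joined = pd.concat([x, y], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 shared days for Kendall tau")
    res = stats.kendalltau(joined.iloc[:, 0], joined.iloc[:, 1], variant="b")
    return float(res.statistic), float(res.pvalue)


def tau_group(
    series: dict[str, pd.Series],
    tau_min: float = 0.5,
    alpha: float = 0.05,
    min_shared: int = 3,
) -> TauGrouping:
    """Single-linkage grouping of emission dynamics on the Kendall-τ graph.

    Two compounds are linked when τ >= tau_min and p < alpha; groups are the
    connected components of the link graph, so a chain A–B, B–C groups
    {A, B, C} even if A–C falls below threshold.  Pairs with fewer than
    ``min_shared`` common days stay unlinked (τ = NaN).
    """
    names = sorted(series)
    tau = pd.DataFrame(np.nan, index=names, columns=names)
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    for name in names:
        if series[name].nunique() > 1:
            tau.loc[name, name] = 1.0
            pmat.loc[name, name] = 0.0

    parent = {n: n for n in names}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in itertools.combinations(names, 2):
        try:
            t, p = kendall_tau(series[a], series[b])
        except ValueError:
            continue
        tau.loc[a, b] = tau.loc[b, a] = t
        pmat.loc[a, b] = pmat.loc[b, a] = p
        if t >= tau_min and p < alpha:
            parent[find(a)] = find(b)

    components: dict[str, set[str]] = {}
    for n in names:
        components.setdefault(find(n), set()).add(n)
    groups = sorted(components.values(), key=lambda g: (-len(g), sorted(g)))
    return TauGrouping(compounds=names, tau=tau, p=pmat, groups=groups)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with a χ²(k−1) p-value.

    All-identical values across groups give H = 0, p = 1 (no evidence of
    any difference) rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def dunn_posthoc(
    groups: dict[str, list],
    alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """Dunn's post-hoc test: pairwise z statistics on mean ranks.

    Ranks are taken over the pooled data; the z statistic for groups i, j is

        z = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j) )

    with tie correction T = Σ(t³ − t) over tied value groups.  P-values are
    two-sided normal, optionally Holm-adjusted.  Returns a DataFrame with
    columns ``group1, group2, z, p, p_adjusted, significant``.
    """
    names = sorted(groups)
    arrays = {k: np.asarray(groups[k], dtype=float) for k in names}
    if any(len(a) == 0 for a in arrays.values()):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate([arrays[k] for k in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    start = 0
    for k in names:
        n_k = len(arrays[k])
        mean_rank[k] = float(ranks[start : start + n_k].mean())
        start += n_k

    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    var_term = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(var_term * (1.0 / len(arrays[a]) + 1.0 / len(arrays[b])))
        if se == 0:  # fully tied data
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z, "p": p})
    out = pd.DataFrame(rows)

    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p"], method="holm")[1]
    elif adjust == "none":
        out["p_adjusted"] = out["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["significant"] = out["p_adjusted"] < alpha
    return out
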