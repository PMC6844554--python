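"""Statistical analyses: nonparametric tests, 4PL fitting, normalization.

Covers everything the downstream figures need: Kruskal-Wallis with Dunn's
post test, the two-group rank test, Spearman correlation, four-parameter
logistic EC50/IC50 fitting on log dose, vehicle-based fold/z
normalization, the large-droplet tail statistic, high/low single-cell
stratification, and comparative-Ct (2^-ddCt) analysis.

Standard tests are delegated to scipy.stats; Dunn's z and the 4PL fitter
are implemented here (with scipy only providing optimization and the
normal/chi-square distributions).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import ConstantInputError, InvalidParameterError
from .fourpl import INHIBITION, STIMULATION, FourPLParams


@dataclass
class StatResult:
    """A test outcome: statistic, p value, group sizes, optional post test."""

    test_name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    pairwise: pd.DataFrame | None = None
    extra: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_sizes": list(self.group_sizes),
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        d.update(self.extra)
        return d


def _clean_groups(groups, min_groups=2):
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < min_groups:
        raise InvalidParameterError(f"need at least {min_groups} groups")
    for a in arrs:
        if a.size == 0:
            raise InvalidParameterError("groups must be non-empty")
    return arrs


def kruskal_wallis(groups) -> StatResult:
    """Rank one-way ANOVA (Kruskal-Wallis H with tie correction).

    All-identical values across groups are a well-defined no-effect case:
    H = 0, p = 1.
    """
    arrs = _clean_groups(groups)
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return StatResult("kruskal_wallis", 0.0, 1.0, tuple(len(a) for a in arrs))
    h, p = sps.kruskal(*arrs)
    return StatResult("kruskal_wallis", float(h), float(p), tuple(len(a) for a in arrs))


def dunn_posttest(groups, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z post test after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]
    with the tie term T = sum(t^3 - t) over tied values in the pooled
    sample. Two-sided normal p values, Bonferroni-multiplied over all
    k(k-1)/2 pairs by default (``adjust="none"`` disables, ``"holm"``
    uses the step-down variant).
    """
    arrs = _clean_groups(groups)
    if adjust not in ("bonferroni", "none", "holm"):
        raise InvalidParameterError(f"unknown adjustment {adjust!r}")
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrs))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    rows = []
    for i, j in itertools.combinations(range(len(arrs)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_i": i, "group_j": j, "z": z, "p": p})
    table = pd.DataFrame(rows)
    m = len(table)
    if adjust == "bonferroni":
        table["p_adj"] = np.minimum(table["p"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(table["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        table["p_adj"] = adj
    else:
        table["p_adj"] = table["p"]
    return table


def mann_whitney(a, b, exact_below: int = 20) -> StatResult:
    """Two-group rank test (Mann-Whitney U), the nonparametric t test.

    Exact enumeration p when both samples are smaller than
    ``exact_below`` and tie-free; the tie-corrected normal approximation
    otherwise. The statistic is U of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size < exact_below and b.size < exact_below and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(
        "mann_whitney",
        float(res.statistic),
        float(res.pvalue),
        (a.size, b.size),
        extra={"method": method},
    )


def spearman(x, y) -> StatResult:
    """Spearman rank correlation (Pearson on tie-averaged ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("Spearman correlation undefined for a constant vector")
    r, p = sps.spearmanr(x, y)
    return StatResult("spearman", float(r), float(p), (x.size,))


# --------------------------------------------------------------------------
# 4PL dose-response fitting
# --------------------------------------------------------------------------


@dataclass
class DoseResponseFit:
    """Result of a four-parameter logistic fit.

    ``params.c50`` is reported as EC50 (stimulation) or IC50 (inhibition);
    ``se`` holds delta-method standard errors keyed by parameter name.
    ``converged`` must be True for the estimate to be trusted;
    ``degenerate`` flags a fit whose asymptotes collapsed (no
    interpretable c50).
    """

    params: FourPLParams | None
    se: dict
    rss: float
    converged: bool
    degenerate: bool
    n: int
    mode: str

    @property
    def c50(self) -> float | None:
        return None if self.params is None else self.params.c50

    @property
    def c50_label(self) -> str:
        return "EC50" if self.mode == STIMULATION else "IC50"

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "rss": self.rss,
            "n": self.n,
        }
        if self.params is not None:
            d.update(
                {
                    "bottom": self.params.bottom,
                    "top": self.params.top,
                    self.c50_label: self.params.c50,
                    "hill": self.params.hill,
                    "se": self.se,
                }
            )
        return d


def _logistic_logd(logd, a0, a_inf, log_c50, hill):
    """Response at log10 dose; a0 = zero-dose asymptote, a_inf = high-dose."""
    return a0 + (a_inf - a0) / (1.0 + 10.0 ** (hill * (log_c50 - logd)))


def fit_4pl(
    dose_nM,
    response,
    mode: str,
    *,
    vehicle_divisor: float = 1000.0,
    hill_bounds: tuple[float, float] = (0.2, 5.0),
    n_starts: int = 7,
) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 dose with multi-start initialization.

    Vehicle (dose 0) observations are included by substituting the
    placeholder dose ``min(positive doses) / vehicle_divisor``, far enough
    below the tested range to act as the zero-dose asymptote. Starting
    c50 values are gridded across the observed dose range and the best
    residual sum of squares wins.
    """
    if mode not in (STIMULATION, INHIBITION):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    dose = np.asarray(dose_nM, dtype=float)
    resp = np.asarray(response, dtype=float)
    if dose.shape != resp.shape or dose.ndim != 1:
        raise InvalidParameterError("dose and response must be equal-length 1-D")
    if np.any(dose < 0):
        raise InvalidParameterError("doses must be non-negative")
    if np.unique(dose).size < 4:
        raise InvalidParameterError("need at least 4 distinct doses (including vehicle)")
    positive = dose[dose > 0]
    if positive.size == 0:
        raise InvalidParameterError("need positive doses")
    placeholder = positive.min() / vehicle_divisor
    logd = np.log10(np.where(dose > 0, dose, placeholder))
    n = dose.size

    if np.ptp(resp) == 0.0:
        return DoseResponseFit(None, {}, 0.0, False, True, n, mode)

    lo, hi = float(np.log10(positive.min())), float(np.log10(positive.max()))
    starts = np.linspace(lo, hi, n_starts)
    bounds = (
        [-np.inf, -np.inf, lo - 3.0, hill_bounds[0]],
        [np.inf, np.inf, hi + 3.0, hill_bounds[1]],
    )
    order = np.argsort(logd)
    a0_guess = float(np.mean(resp[order[:2]]))
    ainf_guess = float(np.mean(resp[order[-2:]]))
    best = None
    for lc in starts:
        try:
            popt, pcov = optimize.curve_fit(
                _logistic_logd,
                logd,
                resp,
                p0=[a0_guess, ainf_guess, lc, 1.0],
                bounds=bounds,
                maxfev=20000,
                ftol=1e-14,
                xtol=1e-14,
                gtol=1e-14,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((_logistic_logd(logd, *popt) - resp) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        return DoseResponseFit(None, {}, math.inf, False, False, n, mode)
    rss, popt, pcov = best
    a0, a_inf, log_c50, hill = popt
    degenerate = abs(a_inf - a0) < 0.05 * np.ptp(resp)
    c50 = 10.0**log_c50
    if mode == STIMULATION:
        params = FourPLParams(bottom=a0, top=a_inf, c50=c50, hill=hill, mode=mode)
    else:
        params = FourPLParams(bottom=a_inf, top=a0, c50=c50, hill=hill, mode=mode)
    se = {}
    if pcov is not None and np.all(np.isfinite(pcov)):
        perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
        zero_name = "bottom" if mode == STIMULATION else "top"
        inf_name = "top" if mode == STIMULATION else "bottom"
        se = {
            zero_name: float(perr[0]),
            inf_name: float(perr[1]),
            "c50": float(math.log(10.0) * c50 * perr[2]),
            "hill": float(perr[3]),
        }
    return DoseResponseFit(params, se, rss, True, bool(degenerate), n, mode)


# --------------------------------------------------------------------------
# normalization, tails, stratification, comparative Ct
# --------------------------------------------------------------------------


def normalize_to_vehicle(values, vehicle_values, mode: str = "fold"):
    """Express values as fold change over, or z score against, vehicle."""
    values = np.asarray(values, dtype=float)
    vehicle = np.asarray(vehicle_values, dtype=float)
    if vehicle.size == 0:
        raise InvalidParameterError("vehicle sample must be non-empty")
    if mode == "fold":
        m = vehicle.mean()
        if m == 0:
            raise InvalidParameterError("vehicle mean is zero; fold change undefined")
        return values / m
    if mode == "zscore":
        sd = vehicle.std(ddof=1) if vehicle.size > 1 else 0.0
        if sd == 0:
            raise InvalidParameterError("vehicle sd is zero; z score undefined")
        return (values - vehicle.mean()) / sd
    raise InvalidParameterError(f"unknown normalization mode {mode!r}")


@dataclass
class LargeDropletResult:
    """Tail statistic: share of droplets beyond vehicle mean + 2 sd."""

    threshold: float
    frac_vehicle: float
    frac_treated: float
    fold_enrichment: float | None  # None when the vehicle tail is empty

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "frac_vehicle": self.frac_vehicle,
            "frac_treated": self.frac_treated,
            "fold_enrichment": self.fold_enrichment,
        }


def large_droplet_fraction(vehicle_areas, treated_areas) -> LargeDropletResult:
    """Fraction of droplet areas strictly above vehicle mean + 2 sd.

    The threshold is defined on the vehicle sample only; the fold
    enrichment is treated over vehicle tail fractions (undefined when no
    vehicle droplet exceeds the threshold).
    """
    v = np.asarray(vehicle_areas, dtype=float)
    t = np.asarray(treated_areas, dtype=float)
    if v.size < 2 or t.size == 0:
        raise InvalidParameterError("need >= 2 vehicle droplets and >= 1 treated")
    thr = v.mean() + 2.0 * v.std(ddof=1)
    fv = float(np.mean(v > thr))
    ft = float(np.mean(t > thr))
    fold = ft / fv if fv > 0 else None
    return LargeDropletResult(float(thr), fv, ft, fold)


@dataclass
class StratificationTable:
    """2x2 percentages of cells high/low on two single-cell measures.

    ``pct`` rows are measure-a {high, low}, columns measure-b {high, low};
    the four cells sum to 100. "High" means strictly above the vehicle
    reference mean; ties count as low.
    """

    pct: pd.DataFrame
    reference_means: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "pct": self.pct.to_dict(),
            "reference_mean_a": self.reference_means[0],
            "reference_mean_b": self.reference_means[1],
            "n": self.n,
        }


def stratify_high_low(values_a, values_b, reference_means) -> StratificationTable:
    """Cross-tabulate cells as high/low on two measures vs vehicle means."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or a.size != b.size:
        raise InvalidParameterError("need equal-length non-empty vectors")
    ref_a, ref_b = float(reference_means[0]), float(reference_means[1])
    hi_a = a > ref_a
    hi_b = b > ref_b
    n = a.size
    pct = pd.DataFrame(
        {
            "high_b": [100.0 * np.mean(hi_a & hi_b), 100.0 * np.mean(~hi_a & hi_b)],
            "low_b": [100.0 * np.mean(hi_a & ~hi_b), 100.0 * np.mean(~hi_a & ~hi_b)],
        },
        index=["high_a", "low_a"],
    )
    return StratificationTable(pct, (ref_a, ref_b), n)


@dataclass
class CtResult:
    """Comparative-Ct outcome per gene: ddCt, fold = 2^-ddCt, t-test p."""

    per_gene: pd.DataFrame  # gene, ddct, fold, p_value, n_vehicle, n_treated
    delta_ct: pd.DataFrame  # sample-level dCt values

    def fold(self, gene: str) -> float:
        row = self.per_gene.loc[self.per_gene["gene"] == gene]
        if row.empty:
            raise InvalidParameterError(f"gene {gene!r} not in Ct table")
        return float(row["fold"].iloc[0])

    def to_dict(self) -> dict:
        return {"per_gene": self.per_gene.to_dict(orient="records")}


def ddct(table: pd.DataFrame, normalizer: str = "ACTB") -> CtResult:
    """Comparative-Ct (2^-ddCt) analysis against a housekeeping normalizer.

    dCt = Ct_target - Ct_normalizer per sample; ddCt = mean treated dCt -
    mean vehicle dCt; fold = 2^-ddCt. Group difference tested with a
    two-sample t test on the dCt values.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(table.columns):
        raise InvalidParameterError(f"Ct table needs columns {sorted(required)}")
    norm = table[table["gene"] == normalizer].set_index("sample")["ct"]
    targets = table[table["gene"] != normalizer]
    missing = set(targets["sample"]) - set(norm.index)
    if missing:
        raise InvalidParameterError(f"samples missing a normalizer row: {sorted(missing)}")
    rows = []
    dct_rows = []
    for gene, sub in targets.groupby("gene", sort=True):
        d = sub["ct"].to_numpy(float) - norm.loc[sub["sample"]].to_numpy(float)
        groups = sub["group"].to_numpy()
        d_veh = d[groups == "vehicle"]
        d_trt = d[groups == "treated"]
        if d_veh.size == 0 or d_trt.size == 0:
            raise InvalidParameterError(f"gene {gene!r} lacks a group")
        dd = d_trt.mean() - d_veh.mean()
        if d_veh.size > 1 and d_trt.size > 1:
            p = float(sps.ttest_ind(d_trt, d_veh).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "gene": gene,
                "ddct": float(dd),
                "fold": float(2.0 ** (-dd)),
                "p_value": p,
                "n_vehicle": int(d_veh.size),
                "n_treated": int(d_trt.size),
            }
        )
        dct_rows.append(
            pd.DataFrame({"gene": gene, "sample": sub["sample"], "group": groups, "dct": d})
        )
    return CtResult(pd.DataFrame(rows), pd.concat(dct_rows, ignore_index=True))
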