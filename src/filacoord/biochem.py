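"""Hyperbolic binding fits, bundling quantification, and the nonparametric
hypothesis tests used to compare conditions.

The binding model is single-site saturation, ``y = Bmax * c / (Kd + c)``:
``Kd`` (the apparent equilibrium dissociation constant) is the polymer
concentration at half-maximal binding, and the fitted curve at ``c = Kd``
equals ``Bmax / 2`` by construction. The fit is iterative nonlinear least
squares in log-parameter space (which keeps both parameters positive),
initialized from the data: ``Bmax`` at the maximal observed binding, ``Kd``
at the concentration nearest half of it.

Group comparisons are nonparametric throughout: Mann-Whitney U for two
groups (exact enumeration for small samples without ties, tie-corrected
normal approximation otherwise), Kruskal-Wallis H for several groups with
Dunn's post-hoc z-comparisons against a reference group, Bonferroni-adjusted
over the comparisons actually performed (raw p-values are co-reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthgen import BindingDataset


@dataclass
class BindingFit:
    kd_app_nM: float
    bmax_pct: float
    residual_sd: float
    ci95_kd_nM: tuple
    n_points: int

    def predict(self, concentrations_uM) -> np.ndarray:
        c = np.asarray(concentrations_uM, dtype=float)
        kd_uM = self.kd_app_nM / 1000.0
        return self.bmax_pct * c / (kd_uM + c)


@dataclass
class TestResult:
    method: str  # mann_whitney | kruskal_wallis | dunn
    statistic: float
    p_value: float
    group_labels: tuple = ()
    adjustment: str = "none"
    p_adjusted: float | None = None


@dataclass
class KruskalDunnResult:
    kruskal: TestResult
    dunn: list

    def to_dataframe(self) -> pd.DataFrame:
        rows = [("all groups", self.kruskal.method, self.kruskal.statistic,
                 self.kruskal.p_value, None)]
        rows += [(" vs ".join(d.group_labels), d.method, d.statistic,
                  d.p_value, d.p_adjusted) for d in self.dunn]
        return pd.DataFrame(rows, columns=["comparison", "method",
                                           "statistic", "p_raw",
                                           "p_adjusted"])


def _coerce_binding(data, frac):
    if isinstance(data, BindingDataset):
        return (np.asarray(data.polymer_concentration_uM, float),
                np.asarray(data.fraction_bound_pct, float))
    if frac is None:
        raise ValueError("pass a BindingDataset or (concentrations, fractions)")
    return np.asarray(data, float), np.asarray(frac, float)


def fit_binding(data, fractions_pct=None, fix_bmax: float | None = None,
                max_kd_factor: float = 10.0) -> BindingFit:
    """Fit ``y = Bmax * c / (Kd + c)`` to fraction-bound data.

    Parameters are optimized in log space (no negative excursions);
    convergence at relative parameter change < 1e-10. The 95% CI on Kd comes
    from the parameter covariance at the optimum. ``fix_bmax`` pins the
    saturation level (e.g. at 100%) instead of fitting it. Raises if the
    data show no curvature (``Kd`` runs beyond ``max_kd_factor`` times the
    largest concentration: linear regime only, Kd unidentifiable).
    """
    c, y = _coerce_binding(data, fractions_pct)
    if len(c) != len(y):
        raise ValueError("concentration and fraction arrays differ in length")
    if len(c) < 4:
        raise ValueError("need at least 4 concentration points")
    if not np.any(c > 0):
        raise ValueError("all concentrations are zero: Kd unidentifiable")

    ymax = float(np.max(y))
    if ymax <= 0:
        raise ValueError("no binding signal (max fraction <= 0)")
    pos = c > 0
    kd0 = float(c[pos][np.argmin(np.abs(y[pos] - ymax / 2.0))])
    kd0 = max(kd0, 1e-6)

    if fix_bmax is None:
        p0 = np.log([kd0, max(ymax, 1e-6)])

        def resid(p):
            kd, bmax = np.exp(p)
            return bmax * c / (kd + c) - y
    else:
        p0 = np.log([kd0])

        def resid(p):
            kd = np.exp(p[0])
            return fix_bmax * c / (kd + c) - y

    sol = optimize.least_squares(resid, p0, xtol=1e-12, ftol=1e-12,
                                 gtol=1e-12)
    kd_uM = float(np.exp(sol.x[0]))
    bmax = float(np.exp(sol.x[1])) if fix_bmax is None else float(fix_bmax)

    if kd_uM > max_kd_factor * c.max():
        raise ValueError(
            "Kd unidentifiable: fitted Kd exceeds the sampled concentration "
            "range (linear regime only)")

    dof = max(len(c) - len(sol.x), 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        sd_logkd = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        sd_logkd = float("inf")
    ci = (kd_uM * np.exp(-1.96 * sd_logkd) * 1000.0,
          kd_uM * np.exp(+1.96 * sd_logkd) * 1000.0)
    return BindingFit(
        kd_app_nM=kd_uM * 1000.0,
        bmax_pct=bmax,
        residual_sd=float(np.sqrt(s2)),
        ci95_kd_nM=ci,
        n_points=len(c),
    )


def bundled_fraction(pellet_intensity: float,
                     supernatant_intensity: float) -> float:
    """Percent of actin pelleted: 100 * pellet / (pellet + supernatant)."""
    if pellet_intensity < 0 or supernatant_intensity < 0:
        raise ValueError("band intensities must be >= 0")
    total = pellet_intensity + supernatant_intensity
    if total == 0:
        raise ValueError("pellet and supernatant intensities are both zero")
    return 100.0 * pellet_intensity / total


def mann_whitney(a, b, labels=("a", "b")) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration when the combined sample size is <= 12 and there are
    no ties; tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("mann_whitney", float(res.statistic),
                      float(res.pvalue), tuple(labels))


def kruskal_dunn(groups: dict, reference: str,
                 adjustment: str = "bonferroni") -> KruskalDunnResult:
    """Kruskal-Wallis H (tie-corrected) + Dunn z vs a reference group.

    ``groups`` maps label -> sample. Groups with fewer than 2 observations
    are excluded with a warning. Dunn p-values are reported raw and
    Bonferroni-adjusted over the comparisons performed.
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not in groups")
    clean = {}
    for label, sample in groups.items():
        sample = np.asarray(sample, dtype=float)
        if len(sample) < 2:
            warnings.warn(f"group {label!r} has < 2 observations; excluded",
                          stacklevel=2)
            continue
        clean[label] = sample
    if reference not in clean:
        raise ValueError("reference group excluded (too few observations)")
    if len(clean) < 3:
        raise ValueError("need at least 3 groups")

    labels = list(clean.keys())
    h, p_kw = stats.kruskal(*clean.values())
    kw = TestResult("kruskal_wallis", float(h), float(p_kw), tuple(labels))

    pooled = np.concatenate([clean[l] for l in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks = {}
    start = 0
    for label in labels:
        n = len(clean[label])
        mean_ranks[label] = ranks[start:start + n].mean()
        start += n
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    comparisons = [l for l in labels if l != reference]
    k = len(comparisons)
    dunn = []
    for label in comparisons:
        se = np.sqrt(base_var * (1.0 / len(clean[reference])
                                 + 1.0 / len(clean[label])))
        z = (mean_ranks[label] - mean_ranks[reference]) / se
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        if adjustment == "bonferroni":
            p_adj = min(1.0, p_raw * k)
        elif adjustment == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown adjustment {adjustment!r}")
        dunn.append(TestResult("dunn", float(z), p_raw,
                               (reference, label), adjustment, p_adj))
    return KruskalDunnResult(kw, dunn)
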