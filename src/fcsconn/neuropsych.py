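"""Composite cognitive-domain Z-scores and cohort-table statistics.

Raw neuropsychological scores are standardized against a reference
population (default: the healthy-control group), sign-aligned so that
higher always means better (timed tests are flipped), and averaged within
each cognitive domain to form composite Z-scores. Group comparisons use a
pooled-variance two-sample t-test for continuous demographics, an
uncorrected Pearson chi-square for 2x2 categorical tables, and an ANCOVA
(linear model with a group term plus age and education covariates) for the
composites — note the cognition ANCOVA covariates deliberately differ from
the age+sex+education set used for FCS maps.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats as sps


class NeuropsychError(ValueError):
    pass


@dataclass(frozen=True)
class TestSpec:
    domain: str
    higher_is_better: bool


def default_catalogue() -> dict[str, TestSpec]:
    """The shipped test catalogue (domain + direction flag per test)."""
    ref = importlib.resources.files("fcsconn").joinpath("data/test_catalogue.yaml")
    raw = yaml.safe_load(ref.read_text())
    return load_catalogue(raw)


def load_catalogue(raw: dict) -> dict[str, TestSpec]:
    tests = raw["tests"] if "tests" in raw else raw
    out = {}
    for name, spec in tests.items():
        if "domain" not in spec or "higher_is_better" not in spec:
            raise NeuropsychError(f"test {name!r} lacks domain or direction flag")
        out[name] = TestSpec(spec["domain"], bool(spec["higher_is_better"]))
    return out


def composite_z(battery: pd.DataFrame, catalogue: dict[str, TestSpec],
                reference: pd.Index | np.ndarray | list) -> pd.DataFrame:
    """Per-subject, per-domain composite Z-scores.

    Each test is z-scored against the reference subjects' mean/SD,
    sign-flipped when ``higher_is_better`` is false, and averaged within
    its domain; a subject's missing tests are excluded from that mean.
    """
    ref = battery.loc[reference]
    if len(ref) < 2:
        raise NeuropsychError("reference subset needs at least 2 subjects")
    domains: dict[str, list[pd.Series]] = {}
    for test in battery.columns:
        if test not in catalogue:
            continue
        spec = catalogue[test]
        sd = ref[test].std(ddof=1)
        if not sd > 0:
            raise NeuropsychError(f"zero reference SD for test {test!r}")
        z = (battery[test] - ref[test].mean()) / sd
        if not spec.higher_is_better:
            z = -z
        domains.setdefault(spec.domain, []).append(z)
    out = pd.DataFrame({
        dom: pd.concat(series, axis=1).mean(axis=1, skipna=True)
        for dom, series in domains.items()
    })
    return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def two_sample_t(x, y) -> TTestResult:
    """Pooled-variance two-sided two-sample t-test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise NeuropsychError("need at least 2 observations per group")
    df = len(x) + len(y) - 2
    pooled = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
    if pooled == 0:
        raise NeuropsychError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df = 1, two-sided p.

    Yates continuity correction is off by default (the convention that
    matches classic cohort-table sex comparisons); pass ``correction=True``
    to enable it.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise NeuropsychError("need a 2x2 table of nonnegative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise NeuropsychError("zero marginal in the 2x2 table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def ancova_domain(scores, group, covariates: pd.DataFrame | None = None
                  ) -> tuple[float, float]:
    """Group-effect F and p from ``score ~ intercept + group + covariates``.

    With an empty covariate set this reduces exactly to the squared
    two-sample t (F = t^2).
    """
    scores = np.asarray(scores, float)
    group = np.asarray(group)
    if group.dtype == object or group.dtype.kind in "US":
        group = (group == "patient").astype(float)
    cols = {"group": group.astype(float)}
    if covariates is not None:
        for name in covariates.columns:
            cols[name] = np.asarray(covariates[name], float)
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise NeuropsychError("rank-deficient ANCOVA design")
    fit = sm.OLS(scores, X).fit()
    if fit.ssr < 1e-20 * float(np.sum(scores ** 2)) + 1e-300:
        return 0.0, 1.0      # exact fit: no residual evidence
    t = fit.tvalues["group"]
    p = fit.pvalues["group"]
    return float(t ** 2), float(p)


def cohort_summary(table: pd.DataFrame,
                   domains=("mmse", "episodic_memory", "executive",
                            "information_processing_speed", "visuospatial")
                   ) -> pd.DataFrame:
    """Cohort demographics/cognition summary with per-row group tests.

    Age and education are compared by pooled t-test, sex by uncorrected
    chi-square, and cognitive composites by ANCOVA with age + education as
    covariates.
    """
    pat = table[table["group"] == "patient"]
    con = table[table["group"] == "control"]
    rows = []

    def _ms(s):
        return f"{s.mean():.1f} ± {s.std(ddof=1):.1f}"

    for name in ("age", "education"):
        res = two_sample_t(pat[name], con[name])
        rows.append((name, _ms(pat[name]), _ms(con[name]), "t-test", res.p))
    counts = [[int((pat["sex"] == 1).sum()), int((pat["sex"] == 0).sum())],
              [int((con["sex"] == 1).sum()), int((con["sex"] == 0).sum())]]
    _, p_sex = chi_square_2x2(counts)
    rows.append(("sex (M/F)", f"{counts[0][0]}/{counts[0][1]}",
                 f"{counts[1][0]}/{counts[1][1]}", "chi-square", p_sex))
    covs = table[["age", "education"]]
    for dom in domains:
        if dom not in table.columns:
            continue
        _, p = ancova_domain(table[dom], table["group"], covs)
        rows.append((dom, _ms(pat[dom]), _ms(con[dom]), "ANCOVA", p))
    return pd.DataFrame(rows, columns=["variable", "patients", "controls",
                                       "test", "p"])
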