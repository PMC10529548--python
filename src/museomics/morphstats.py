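"""Univariate tests and PCA on meristic (scale-count) characters.

Two-population species-delimitation statistics: chi-squared and Fisher's
exact tests on dichotomised count classes, two-way ANOVA (population x sex)
on counts, ANCOVA on tail length with snout-vent length as covariate, and a
PCA of standardised characters to visualise overall phenotype. Sums of
squares are sequential (Type I) in the order covariate, population, sex,
interaction; the SS type is exposed because the data are unbalanced.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf


@dataclass
class TestResult:
    effect: str
    statistic: float
    df: float | tuple
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 + 1e-12):
            raise ValueError("p-value outside [0, 1]")
        self.p_value = min(self.p_value, 1.0)


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # characters x components
    scores: np.ndarray  # specimens x components
    percent_variance: np.ndarray
    characters: list[str]
    specimen_ids: list[str]


def chisq_2x2(table, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on a 2x2 table.

    With continuity_correction, |O-E| is reduced by 0.5 (Yates). Zero margins
    are an error (use Fisher's exact test instead).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin: chi-squared undefined, use fisher_exact_2x2")
    expected = np.outer(row, col) / n
    dev = np.abs(obs - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    x2 = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(x2, df=1))
    return TestResult("independence", x2, 1, p)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test: sum of hypergeometric probabilities of
    all tables with the observed margins that are no more probable than the
    observed table."""
    obs = np.asarray(table, dtype=int)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    a = obs[0, 0]
    r1, r2 = obs.sum(axis=1)
    c1 = obs[:, 0].sum()
    n = obs.sum()
    if n == 0:
        return TestResult("association", math.nan, (), 1.0)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return TestResult("association", math.nan, (), min(p, 1.0))


def fisher_exact_rxc(table, max_tables: int = 2_000_000) -> TestResult:
    """Exact conditional test on an r x c table by full enumeration of all
    tables with the observed margins (suitable for the small specimen counts
    involved here)."""
    obs = np.asarray(table, dtype=int)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)

    def log_table_prob(t: np.ndarray, lognorm: float) -> float:
        return lognorm - sum(math.lgamma(v + 1) for v in t.ravel())

    lognorm = (
        sum(math.lgamma(v + 1) for v in rows)
        + sum(math.lgamma(v + 1) for v in cols)
        - math.lgamma(obs.sum() + 1)
    )
    p_obs = log_table_prob(obs, lognorm)
    total = 0.0
    count = 0

    def fill(row_idx: int, remaining_cols: np.ndarray, built: list):
        nonlocal total, count
        if count > max_tables:
            raise RuntimeError("enumeration too large; use a Monte-Carlo test")
        if row_idx == len(rows) - 1:
            t = np.vstack(built + [remaining_cols])
            if (remaining_cols >= 0).all():
                count += 1
                lp = log_table_prob(t, lognorm)
                if lp <= p_obs + 1e-9:
                    total += math.exp(lp)
            return
        r = rows[row_idx]
        ncols = len(cols)

        def cells(pos: int, left: int, row: list):
            if pos == ncols - 1:
                if 0 <= left <= remaining_cols[pos]:
                    fill(row_idx + 1, remaining_cols - np.array(row + [left]), built + [np.array(row + [left])])
                return
            for v in range(min(left, remaining_cols[pos]) + 1):
                cells(pos + 1, left - v, row + [v])

        cells(0, r, [])

    fill(0, cols.copy(), [])
    return TestResult("association", math.nan, (), min(total, 1.0))


def _sequential_anova(
    data: pd.DataFrame, response: str, terms: list[tuple[str, str]]
) -> list[TestResult]:
    """Type I (sequential) decomposition by nested OLS fits in the declared
    term order (a single-formula anova table would let the design-matrix
    builder reorder terms, silently changing the decomposition)."""
    rhs: list[str] = []
    fits = [smf.ols(f"{response} ~ 1", data=data).fit()]
    for _, term in terms:
        rhs.append(term)
        fits.append(smf.ols(f"{response} ~ {' + '.join(rhs)}", data=data).fit())
    full = fits[-1]
    ms_resid = full.ssr / full.df_resid if full.df_resid > 0 else math.nan
    ss_total = float(fits[0].ssr)
    out = []
    for k, (effect, _) in enumerate(terms):
        ss = fits[k].ssr - fits[k + 1].ssr
        df_num = fits[k].df_resid - fits[k + 1].df_resid
        # an effect explaining essentially none of the variation is reported
        # as F = 0 rather than a 0/0 round-off artefact
        if df_num <= 0 or ss < 1e-9 * max(ss_total, 1e-300):
            out.append(TestResult(effect, 0.0, (df_num, full.df_resid), 1.0))
            continue
        f = (ss / df_num) / ms_resid
        p = float(stats.f.sf(f, df_num, full.df_resid))
        out.append(TestResult(effect, float(f), (df_num, full.df_resid), p))
    return out


def two_way_anova(
    data: pd.DataFrame, y: str, factor_a: str = "population", factor_b: str = "sex"
) -> list[TestResult]:
    """Two-way ANOVA with sequential (Type I) SS in order A, B, A x B.

    Rows with missing y, factor_a or factor_b are dropped listwise. If a cell
    of the two-way layout is empty the interaction term is omitted.
    """
    d = data[[y, factor_a, factor_b]].dropna()
    if d[factor_a].nunique() < 2:
        raise ValueError(f"factor {factor_a!r} needs >= 2 observed levels")
    if d[factor_b].nunique() < 2:
        # constant second factor: reduces to one-way ANOVA on factor_a
        return _sequential_anova(d, y, [(factor_a, f"C({factor_a})")])
    cells = d.groupby([factor_a, factor_b], observed=True).size()
    full_layout = d[factor_a].nunique() * d[factor_b].nunique()
    with_interaction = len(cells) == full_layout
    terms = [
        (factor_a, f"C({factor_a})"),
        (factor_b, f"C({factor_b})"),
    ]
    if with_interaction:
        terms.append((f"{factor_a}:{factor_b}", f"C({factor_a}):C({factor_b})"))
    else:
        warnings.warn(
            f"empty cell in the {factor_a} x {factor_b} layout: interaction omitted"
        )
    return _sequential_anova(d, y, terms)


def two_way_ancova(
    data: pd.DataFrame,
    y: str = "TL",
    covariate: str = "SVL",
    factor_a: str = "population",
    factor_b: str = "sex",
) -> list[TestResult]:
    """Two-way ANCOVA: y ~ covariate + A + B + A x B, sequential SS with the
    covariate entered first."""
    d = data[[y, covariate, factor_a, factor_b]].dropna()
    if d[covariate].nunique() < 2:
        raise ValueError("covariate is degenerate (zero variance)")
    terms = [
        (covariate, covariate),
        (factor_a, f"C({factor_a})"),
        (factor_b, f"C({factor_b})"),
        (f"{factor_a}:{factor_b}", f"C({factor_a}):C({factor_b})"),
    ]
    return _sequential_anova(d, y, terms)


DEFAULT_PCA_CHARACTERS = ["midbody_rows", "nape_rows", "ventrals", "subcaudals"]


def pca_standardized(
    data: pd.DataFrame, characters: list[str] | None = None
) -> PcaResult:
    """PCA by SVD of the covariance of standardised characters.

    Specimens missing any selected character are excluded (complete-case).
    Each character is centred and scaled to unit sample SD (n-1), so the
    analysed covariance is the correlation matrix and eigenvalues sum to the
    number of characters. Each eigenvector's largest-magnitude loading is
    made positive for sign stability.
    """
    characters = characters or DEFAULT_PCA_CHARACTERS
    d = data.dropna(subset=characters)
    if len(d) < 3:
        raise ValueError("fewer than 3 complete-case specimens")
    X = d[characters].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [c for c, s in zip(characters, sd) if s == 0]
        raise ValueError(f"zero-variance characters: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    # SVD of the standardised data gives the eigen-decomposition of its
    # covariance: eigenvalues s^2/(n-1), eigenvectors the right singular vectors
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (len(Z) - 1)
    vecs = vt.T
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = Z @ vecs
    pct = eigvals / eigvals.sum() * 100.0
    ids = d["specimen_id"].tolist() if "specimen_id" in d else [str(i) for i in d.index]
    return PcaResult(eigvals, vecs, scores, pct, list(characters), ids)


# ---------------------------------------------------------------------------
# Dichotomisation used by the categorical tests


def dichotomise(series: pd.Series, cut: float) -> pd.Series:
    """Split counts into two classes: <= cut vs > cut (published class
    boundaries: midbody 17-18 vs 19; nape 16-18 vs 19)."""
    s = series.dropna()
    return (s > cut).map({False: f"<={cut:g}", True: f">{cut:g}"})


def contingency(data: pd.DataFrame, character: str, cut: float, by: str = "population") -> np.ndarray:
    """2 x k contingency table of dichotomised character by group."""
    d = data.dropna(subset=[character])
    classes = dichotomise(d[character], cut)
    tab = pd.crosstab(d[by], classes)
    return tab.to_numpy()
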