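"""Statistical stage: outlier screening, mixed models, Tukey HSD, PCA.

Repeatedly measured traits are analysed with a linear mixed model with
browsing treatment (T), species (S), campaign date (D) and all their
interactions as fixed effects and a plant-level random intercept for the
repeated measurements.  Models are simplified by backward elimination to
the minimal adequate model: at each step the least significant currently
droppable term (one not contained in a retained higher-order interaction)
with P >= alpha is removed and the model refitted.

Fixed-effect P values use marginal Wald F tests with sum-to-zero contrasts
and containment denominator degrees of freedom: terms varying only between
plants are tested against the plant stratum, terms involving date against
the within-plant stratum.  On balanced designs this reproduces classical
split-plot F tests.

Once-measured traits use the same selection loop on ordinary linear
models.  The ordination stage is a PCA on the z-scored per-plant table of
the treatment-responsive traits.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "OutlierReport",
    "flag_extreme_outliers",
    "screen_trait_table",
    "ModelSpec",
    "ModelResult",
    "fit_lmm_backward",
    "fit_lm_oneshot",
    "tukey_dates",
    "PCAResult",
    "run_pca",
    "PCA_TRAITS",
]

FACTOR_COLUMNS = {"T": "treatment", "S": "species", "D": "date"}
_FACTOR_EXPR = {
    "T": "C(treatment, Sum)",
    "S": "C(species, Sum)",
    "D": "C(date, Sum)",
}

#: the treatment-responsive traits entering the ordination
PCA_TRAITS = (
    "g_s",
    "a_mass",
    "lma",
    "n_conc",
    "pi_100",
    "pi_0",
    "dw_tw",
    "eps_max",
    "sa_la",
    "sb",
)


# --------------------------------------------------------------------------
# extreme-outlier screening
# --------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Fences and flags for one trait vector."""

    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    extreme: np.ndarray  # outside the fences
    removal: np.ndarray  # beyond removal_ratio x the nearer fence
    ratios: np.ndarray  # |value| / |nearer fence| for extreme values, else 0


def flag_extreme_outliers(
    values,
    fence_multiplier: float = 3.0,
    removal_ratio: float = 10.0,
) -> OutlierReport:
    """Flag extreme outliers by the interquartile-range rule.

    Quartiles use linear interpolation (numpy default, the common "type 7"
    convention).  A value outside ``[Q1 - m*IQR, Q3 + m*IQR]`` with
    ``m = fence_multiplier`` is *extreme*; an extreme value whose magnitude
    additionally exceeds ``removal_ratio`` times the magnitude of the fence
    it crossed is flagged *for removal*.  A constant vector has no spread
    and nothing is flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values to place fences")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    extreme = np.zeros(x.size, dtype=bool)
    removal = np.zeros(x.size, dtype=bool)
    ratios = np.zeros(x.size)
    if iqr <= 0:
        return OutlierReport(q1, q3, 0.0, q1, q3, extreme, removal, ratios)
    lower = q1 - fence_multiplier * iqr
    upper = q3 + fence_multiplier * iqr
    hi = x > upper
    lo = x < lower
    extreme = hi | lo
    fence = np.where(hi, upper, lower)
    ratios = np.zeros(x.size)
    if extreme.any():
        with np.errstate(divide="ignore"):
            ratios[extreme] = np.abs(x[extreme]) / np.abs(fence[extreme])
    removal = extreme & (ratios > removal_ratio)
    return OutlierReport(
        float(q1), float(q3), float(iqr), float(lower), float(upper),
        extreme, removal, ratios,
    )


def screen_trait_table(
    table: pd.DataFrame,
    group_cols: tuple[str, ...] = ("trait", "species", "treatment"),
    fence_multiplier: float = 3.0,
    removal_ratio: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen a long trait table group-wise; drop values flagged for removal.

    Fences are placed within species x treatment cells of each trait:
    trait scales differ between the species by up to an order of magnitude,
    so pooled fences would be dominated by the species contrast rather than
    by measurement anomalies.

    Returns ``(clean_table, report)`` where the report lists every flagged
    value with its fence ratio and whether it was removed.
    """
    table = table.reset_index(drop=True)
    reports = []
    keep = np.ones(len(table), dtype=bool)
    for key, grp in table.groupby(list(group_cols), sort=True, dropna=False):
        vals = grp["value"].to_numpy()
        if np.sum(np.isfinite(vals)) < 4:
            continue
        rep = flag_extreme_outliers(vals, fence_multiplier, removal_ratio)
        if not rep.extreme.any():
            continue
        for local_i in np.where(rep.extreme)[0]:
            row = grp.iloc[local_i]
            reports.append(
                {
                    **dict(zip(group_cols, key if isinstance(key, tuple) else (key,))),
                    "plant_id": row.get("plant_id", ""),
                    "value": row["value"],
                    "fence_ratio": rep.ratios[local_i],
                    "removed": bool(rep.removal[local_i]),
                }
            )
        removal_idx = grp.index[rep.removal]
        keep[table.index.get_indexer(removal_idx)] = False
    report = pd.DataFrame(
        reports,
        columns=[*group_cols, "plant_id", "value", "fence_ratio", "removed"],
    )
    return table.loc[keep].reset_index(drop=True), report


# --------------------------------------------------------------------------
# model specification and backward selection
# --------------------------------------------------------------------------

Term = frozenset


def _all_terms(factors: tuple[str, ...]) -> list[Term]:
    terms = []
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            terms.append(frozenset(combo))
    return terms


def term_label(term: Term) -> str:
    return ":".join(f for f in ("T", "S", "D") if f in term)


def _term_expr(term: Term) -> str:
    return ":".join(_FACTOR_EXPR[f] for f in ("T", "S", "D") if f in term)


@dataclass
class ModelSpec:
    """Response trait, fixed-effect factors and selection settings."""

    response: str
    factors: tuple[str, ...] = ("T", "S", "D")
    random_intercept: bool = True
    alpha: float = 0.05
    transform: str = "auto"  # none | log10 | auto

    def __post_init__(self) -> None:
        for f in self.factors:
            if f not in FACTOR_COLUMNS:
                raise ValueError(f"unknown factor {f!r}")
        if self.transform not in ("none", "log10", "auto"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class ModelResult:
    """Retained terms, P values and the elimination path of one model."""

    response: str
    retained: list[str]
    pvalues: dict[str, float]
    path: list[dict]
    transform: str
    sign_flipped: bool
    random_intercept: bool
    alpha: float
    diagnostics: dict = field(default_factory=dict)

    def term_significant(self, label: str) -> bool:
        return label in self.retained and self.pvalues.get(label, 1.0) < self.alpha


def _prepare_response(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, str, bool]:
    df = table.copy()
    df = df[np.isfinite(df["value"])]
    transform = spec.transform
    flipped = False
    if transform == "auto":
        transform = "none"  # decided later against the full model
    if transform == "log10":
        df, flipped = _apply_log10(df)
    return df.reset_index(drop=True), transform, flipped


def _apply_log10(df: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    vals = df["value"].to_numpy()
    if np.all(vals > 0):
        df = df.assign(value=np.log10(vals))
        return df, False
    if np.all(vals < 0):
        # negative-valued traits (water and osmotic potentials): transform
        # the magnitude and restore the sign so directions stay comparable
        df = df.assign(value=-np.log10(-vals))
        return df, True
    raise ValueError("log10 transform needs a single-signed response")


def _fit_model(df: pd.DataFrame, terms: list[Term], random_intercept: bool):
    rhs = " + ".join(_term_expr(t) for t in sorted(terms, key=len)) or "1"
    formula = f"value ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if random_intercept:
            model = smf.mixedlm(formula, df, groups=df["plant_id"])
            res = model.fit(reml=True)
        else:
            res = smf.ols(formula, df).fit()
    return res


def _containment_df(
    terms: list[Term], slices: dict, n_obs: int, n_groups: int
) -> dict[Term, float]:
    """nlme-style denominator df: between-plant vs within-plant strata."""
    q = {t: slices[_term_expr(t)].stop - slices[_term_expr(t)].start for t in terms}
    p_between = 1 + sum(q[t] for t in terms if "D" not in t)
    p_within = sum(q[t] for t in terms if "D" in t)
    df_between = max(1, n_groups - p_between)
    df_within = max(1, n_obs - n_groups - p_within)
    return {t: (df_within if "D" in t else df_between) for t in terms}


def _term_pvalues(
    res, terms: list[Term], random_intercept: bool, n_obs: int, n_groups: int
) -> dict[Term, float]:
    slices = res.model.data.design_info.term_name_slices
    beta = np.asarray(res.fe_params if random_intercept else res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)[: beta.size, : beta.size]
    if random_intercept:
        ddf = _containment_df(terms, slices, n_obs, n_groups)
    else:
        ddf = {t: float(res.df_resid) for t in terms}
    out = {}
    for t in terms:
        sl = slices[_term_expr(t)]
        b = beta[sl]
        v = cov[sl, sl.start : sl.stop]
        q = b.size
        try:
            w = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            out[t] = 1.0
            continue
        f_stat = w / q
        out[t] = float(scipy.stats.f.sf(f_stat, q, ddf[t]))
    return out


def _needs_log10(res) -> bool:
    """Residual-normality or heteroscedasticity failure on the full model."""
    resid = np.asarray(res.resid, dtype=float)
    fitted = np.asarray(res.fittedvalues, dtype=float)
    resid = resid[np.isfinite(resid)]
    if resid.size < 8:
        return False
    p_norm = scipy.stats.shapiro(resid[:5000]).pvalue
    rho, p_var = scipy.stats.spearmanr(np.abs(resid), fitted[: resid.size])
    return p_norm < 0.05 or (p_var < 0.05 and abs(rho) > 0.2)


def _backward_loop(
    df: pd.DataFrame,
    spec: ModelSpec,
    random_intercept: bool,
) -> tuple[list[Term], dict[Term, float], list[dict], dict]:
    terms = _all_terms(spec.factors)
    n_obs = len(df)
    n_groups = df["plant_id"].nunique()
    diagnostics: dict = {}
    path: list[dict] = []
    while True:
        try:
            res = _fit_model(df, terms, random_intercept)
        except (np.linalg.LinAlgError, ValueError):
            if random_intercept:
                # singular mixed fit: retry the whole path without the
                # random intercept and flag it
                diagnostics["singular_random_intercept"] = True
                random_intercept = False
                res = _fit_model(df, terms, random_intercept)
            else:
                raise
        if random_intercept and float(np.asarray(res.cov_re).ravel()[0]) < 1e-10:
            diagnostics["near_zero_random_variance"] = True
        pvals = _term_pvalues(res, terms, random_intercept, n_obs, n_groups)
        droppable = [
            t
            for t in terms
            if not any(t < other for other in terms)
        ]
        candidates = [t for t in droppable if pvals[t] >= spec.alpha]
        if not candidates:
            break
        worst = max(candidates, key=lambda t: pvals[t])
        path.append({"dropped": term_label(worst), "p": pvals[worst]})
        terms.remove(worst)
        if not terms:
            pvals = {}
            break
    diagnostics["random_intercept_used"] = random_intercept
    return terms, pvals, path, diagnostics


def _validate_levels(df: pd.DataFrame, factors: tuple[str, ...]) -> None:
    for f in factors:
        col = FACTOR_COLUMNS[f]
        if df[col].nunique() < 2:
            raise ValueError(f"factor {f} ({col}) needs >= 2 levels")


def fit_lmm_backward(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Backward-selected linear mixed model for a repeated-measure trait.

    ``table`` is long format with columns ``plant_id, species, treatment,
    date, value`` for a single trait.
    """
    df, transform, flipped = _prepare_response(table, spec)
    _validate_levels(df, spec.factors)
    if spec.transform == "auto":
        full = _fit_model(df, _all_terms(spec.factors), spec.random_intercept)
        if _needs_log10(full):
            df, flipped = _apply_log10(df)
            transform = "log10"
    terms, pvals, path, diagnostics = _backward_loop(df, spec, spec.random_intercept)
    return ModelResult(
        response=spec.response,
        retained=[term_label(t) for t in sorted(terms, key=lambda t: (len(t), term_label(t)))],
        pvalues={term_label(t): p for t, p in pvals.items()},
        path=path,
        transform=transform,
        sign_flipped=flipped,
        random_intercept=diagnostics.get("random_intercept_used", spec.random_intercept),
        alpha=spec.alpha,
        diagnostics=diagnostics,
    )


def fit_lm_oneshot(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Backward-selected ordinary linear model for a once-measured trait.

    Single-factor specifications (the root traits, measured only in the
    excavated deciduous species) refuse tables containing more than one
    species.
    """
    if "S" not in spec.factors and table["species"].nunique() > 1:
        raise ValueError(
            f"{spec.response}: single-species model given multiple species "
            "(root traits are measured in one species only)"
        )
    spec = ModelSpec(
        response=spec.response,
        factors=spec.factors,
        random_intercept=False,
        alpha=spec.alpha,
        transform=spec.transform,
    )
    df, transform, flipped = _prepare_response(table, spec)
    _validate_levels(df, spec.factors)
    if spec.transform == "auto":
        full = _fit_model(df, _all_terms(spec.factors), False)
        if _needs_log10(full):
            df, flipped = _apply_log10(df)
            transform = "log10"
    terms, pvals, path, diagnostics = _backward_loop(df, spec, False)
    return ModelResult(
        response=spec.response,
        retained=[term_label(t) for t in sorted(terms, key=lambda t: (len(t), term_label(t)))],
        pvalues={term_label(t): p for t, p in pvals.items()},
        path=path,
        transform=transform,
        sign_flipped=flipped,
        random_intercept=False,
        alpha=spec.alpha,
        diagnostics=diagnostics,
    )


# --------------------------------------------------------------------------
# Tukey HSD across dates
# --------------------------------------------------------------------------

def tukey_dates(result: ModelResult, table: pd.DataFrame, alpha: float = 0.05):
    """All pairwise date comparisons with family-wise adjusted P values.

    Only meaningful when the date effect was retained as significant; the
    comparison is run on the same response scale the model used.

    Returns ``(pairs, letters)``: a DataFrame of pairwise results and a
    compact letter display mapping each date to its group letters (dates
    sharing a letter are not significantly different).
    """
    if not result.term_significant("D"):
        raise ValueError(
            f"{result.response}: date effect not retained at alpha="
            f"{result.alpha}; Tukey comparisons are not applicable"
        )
    df = table[np.isfinite(table["value"])].copy()
    if result.transform == "log10":
        df, _ = _apply_log10(df)
    hsd = pairwise_tukeyhsd(df["value"].to_numpy(), df["date"].to_numpy(), alpha=alpha)
    pairs = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    )
    letters = _compact_letters(hsd, df)
    return pairs, letters


def _compact_letters(hsd, df: pd.DataFrame) -> dict[str, str]:
    groups = list(hsd.groupsunique)
    n = len(groups)
    same = np.ones((n, n), dtype=bool)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            same[i, j] = same[j, i] = not hsd.reject[k]
            k += 1
    # maximal cliques of the not-different graph (n is small)
    cliques: list[frozenset[int]] = []
    for r in range(n, 0, -1):
        for combo in itertools.combinations(range(n), r):
            if all(same[i, j] for i, j in itertools.combinations(combo, 2)):
                s = frozenset(combo)
                if not any(s <= c for c in cliques):
                    cliques.append(s)
    means = df.groupby("date")["value"].mean()
    order = sorted(range(len(cliques)), key=lambda c: means[[groups[i] for i in cliques[c]]].mean())
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for letter_i, c in enumerate(order):
        for i in cliques[c]:
            out[groups[i]] += alphabet[letter_i]
    return {g: "".join(sorted(s)) for g, s in out.items()}


# --------------------------------------------------------------------------
# ordination
# --------------------------------------------------------------------------

@dataclass
class PCAResult:
    loadings: pd.DataFrame  # traits x components
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # per plant, with species/treatment labels
    dropped_plants: list[str]
    rank_deficient: bool


def run_pca(table: pd.DataFrame, traits: tuple[str, ...] = PCA_TRAITS) -> PCAResult:
    """PCA on the z-scored per-plant table of the selected traits.

    Repeatedly measured traits enter as per-plant means across all dates.
    Plants with any missing trait are dropped (and reported).  Component
    signs follow the convention that each component's largest-magnitude
    loading is positive.
    """
    sub = table[table["trait"].isin(traits)]
    wide = (
        sub.groupby(["plant_id", "trait"])["value"].mean().unstack("trait")
    )
    missing_traits = [t for t in traits if t not in wide.columns]
    if missing_traits:
        raise ValueError(f"traits absent from table: {missing_traits}")
    wide = wide[list(traits)]
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if len(complete) < 3:
        raise ValueError("need at least 3 plants with complete trait sets")
    x = complete.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        zero = [traits[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"constant traits cannot be standardized: {zero}")
    z = (x - x.mean(axis=0)) / sd
    rank = np.linalg.matrix_rank(z)
    rank_deficient = rank < min(z.shape)
    pca = PCA()
    scores = pca.fit_transform(z)
    loadings = pca.components_.T  # traits x components
    # orientation convention
    for c in range(loadings.shape[1]):
        imax = np.argmax(np.abs(loadings[:, c]))
        if loadings[imax, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    loadings_df = pd.DataFrame(loadings, index=list(traits), columns=comp_names)
    labels = (
        table[["plant_id", "species", "treatment"]]
        .drop_duplicates("plant_id")
        .set_index("plant_id")
    )
    scores_df = pd.DataFrame(scores, index=complete.index, columns=comp_names)
    scores_df = scores_df.join(labels).reset_index()
    return PCAResult(
        loadings=loadings_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores_df,
        dropped_plants=list(dropped),
        rank_deficient=bool(rank_deficient),
    )
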