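"""Quantification and differential statistics over voted sudo_EMFs.

The quantitative unit is the EMF x sample matrix: per-sample isotopologue
(IMF) intensities are median-normalized within each sample, missing cells are
imputed to half the smallest normalized value in the study, IMF intensities
are summed per EMF and log2-transformed.  Differential abundance is a linear
model of log2 intensity on condition with labeling status and block group as
blocked covariates, with optional empirical-Bayes variance moderation across
EMFs.  Category-level enrichment is an exact sign-binomial test on fold-change
directions with Bonferroni correction, and EMF-EMF association is a Pearson
correlation weighted by information content and consistency of the shared
missingness pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .chem import formula_to_string
from .consensus import SampleSpectrum
from .library import NOT_CATEGORIZED, NOT_LIPID
from .study import SampleMeta
from .voting import MULTIPLE, SudoEMF

logger = logging.getLogger(__name__)

EXCLUDED_CATEGORIES = (MULTIPLE, NOT_LIPID, NOT_CATEGORIZED)


@dataclass(frozen=True)
class StatsConfig:
    sig_threshold: float = 0.1
    null_prob: float = 0.5
    moderated: bool = True
    linear_fold_change: bool = True

    def __post_init__(self):
        if not 0.0 < self.sig_threshold < 1.0:
            raise ValueError("sig_threshold must be in (0, 1)")


@dataclass
class EMFIntensityTable:
    """log2 EMF x sample intensities with imputation mask and row annotation.

    ``imputed`` marks cells where the EMF was entirely absent from the sample
    (every member IMF imputed); ``category`` and ``emf_mz`` are per-row.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame
    category: pd.Series
    emf_mz: pd.Series


def quantify_sudo_emfs(
    sudos: list[SudoEMF], spectra: dict[str, SampleSpectrum]
) -> pd.DataFrame:
    """Raw IMF x sample intensity matrix from voted sudo_EMFs.

    Rows are (sudo index, isotopologue) pairs; each member sample contributes
    the consensus intensity of its matched peak, NaN where absent.
    """
    sample_ids = sorted(spectra)
    rows = {}
    for si, sudo in enumerate(sudos):
        per_heavy: dict[tuple, dict[str, float]] = {}
        for sid in sorted(sudo.members):
            g = sudo.members[sid]
            pool = [c for c in g.candidates if c.emf in sudo.retained_emfs]
            if not pool:
                pool = g.candidates
            best = max(pool, key=lambda c: c.score)
            for heavy, m in best.matched.items():
                per_heavy.setdefault(heavy, {})[sid] = m.intensity
        for heavy in sorted(per_heavy):
            rows[(si, heavy)] = per_heavy[heavy]
    if not rows:
        return pd.DataFrame(
            columns=sample_ids,
            index=pd.MultiIndex.from_arrays([[], []], names=["sudo", "heavy"]),
        )
    # from_dict builds its own (possibly reordered) MultiIndex from the tuple
    # keys; keep it rather than overriding with insertion order
    mat = pd.DataFrame.from_dict(rows, orient="index")
    mat = mat.reindex(columns=sample_ids)
    mat.index = mat.index.set_names(["sudo", "heavy"])
    return mat


def normalize_and_impute(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-normalize per sample, then impute NaNs to (global minimum)/2.

    Each column is divided by the median of its observed values, so the
    per-sample median after normalization is exactly 1.  All-missing samples
    are dropped with a warning.  Returns (normalized matrix, imputation mask).
    """
    norm = raw.copy().astype(float)
    drop = []
    for col in norm.columns:
        med = norm[col].median(skipna=True)
        if not np.isfinite(med) or med <= 0:
            logger.warning("sample %s has no usable peaks; excluded", col)
            drop.append(col)
            continue
        norm[col] = norm[col] / med
    norm = norm.drop(columns=drop)
    mask = norm.isna()
    global_min = np.nanmin(norm.values)
    norm = norm.fillna(global_min / 2.0)
    return norm, mask


def aggregate_emf_log2(
    normalized: pd.DataFrame,
    mask: pd.DataFrame,
    sudos: list[SudoEMF],
) -> EMFIntensityTable:
    """Sum member IMF intensities per EMF and log2-transform.

    Row names are the top-scoring retained formula of each sudo_EMF; a cell is
    flagged imputed when every member IMF of that EMF was imputed in that
    sample.  The EMF m/z is the minimum member IMF m/z across samples.
    """
    sums = normalized.groupby(level="sudo").sum()
    all_imp = mask.groupby(level="sudo").all()
    names, cats, mzs = [], [], []
    for si in sums.index:
        sudo = sudos[si]
        top = max(
            sudo.retained_emfs,
            key=lambda e: (sudo.emf_scores.get(e, 0.0), formula_to_string(e)),
        )
        name = formula_to_string(top)
        if name in names:  # disambiguate rare duplicate winners
            name = f"{name}#{si}"
        names.append(name)
        cats.append(sudo.category)
        mzs.append(sudo.emf_mz)
    values = np.log2(sums)
    values.index = names
    all_imp.index = names
    return EMFIntensityTable(
        values=values,
        imputed=all_imp,
        category=pd.Series(cats, index=names, name="category"),
        emf_mz=pd.Series(mzs, index=names, name="emf_mz"),
    )


def design_matrix(metas: list[SampleMeta], sample_ids: list[str]) -> pd.DataFrame:
    """Intercept + condition(case) + labeled + block-group dummies.

    Blocked covariate columns that are aliased (e.g. labeling assigned per
    block group) are dropped with a log note; an aliased condition column
    raises instead, naming the aliased terms.
    """
    by_id = {m.sample_id: m for m in metas}
    rows = []
    for sid in sample_ids:
        m = by_id[sid]
        rows.append(
            {
                "intercept": 1.0,
                "condition": 1.0 if m.condition == "case" else 0.0,
                "labeled": 0.0 if m.labeling == "unlabeled" else 1.0,
                "group2": 1.0 if m.block_group == 2 else 0.0,
                "group3": 1.0 if m.block_group == 3 else 0.0,
            }
        )
    X = pd.DataFrame(rows, index=sample_ids)
    # drop aliased blocked covariates (condition and intercept are protected)
    protected = ["intercept", "condition"]
    kept = list(X.columns)
    while np.linalg.matrix_rank(X[kept].values) < len(kept):
        droppable = [c for c in kept if c not in protected]
        dropped = False
        for c in reversed(droppable):
            trial = [k for k in kept if k != c]
            if np.linalg.matrix_rank(X[trial].values) == len(trial):
                logger.info("dropping aliased blocked covariate %r", c)
                kept = trial
                dropped = True
                break
        if not dropped:
            aliased = [c for c in kept if c not in ("intercept",)]
            raise ValueError(f"rank-deficient design; aliased terms among {aliased}")
    return X[kept]


def _trigamma_inverse(y: float) -> float:
    # Newton iteration for x with polygamma(1, x) = y
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = max(x + step, 1e-8)
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def _moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes squeezing of residual variances (method of moments on
    the log scale).  Returns (posterior variances, prior df)."""
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    var_e = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if var_e <= 0:
        d0 = np.inf
        s02 = float(np.exp(np.mean(e)))
        return np.full_like(s2, s02), 1e6
    d0 = 2.0 * _trigamma_inverse(var_e)
    s02 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0


def fit_blocked_model(
    table: EMFIntensityTable,
    metas: list[SampleMeta],
    config: StatsConfig = StatsConfig(),
) -> pd.DataFrame:
    """Per-EMF linear model of log2 intensity on condition + blocked covariates.

    With ``config.moderated`` the residual variances are squeezed toward a
    pooled prior before the t-test on the condition coefficient (ordinary
    least-squares t otherwise).  Returns a DataFrame with the condition
    coefficient, raw p, and significance at ``sig_threshold``.
    """
    sample_ids = list(table.values.columns)
    conditions = {m.sample_id: m.condition for m in metas}
    for cond in ("case", "control"):
        if sum(conditions[s] == cond for s in sample_ids) < 2:
            raise ValueError(f"need >= 2 samples in condition {cond!r}")
    design = design_matrix(metas, sample_ids)
    X = design.values
    Y = table.values.values  # (n_emf, n_samples)
    n, p = X.shape
    if n <= p:
        raise ValueError("more model terms than samples")
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv  # (n_emf, p)
    resid = Y - B @ X.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df
    ci = list(design.columns).index("condition")
    se_unit = np.sqrt(xtx_inv[ci, ci])
    if config.moderated:
        s2_post, d0 = _moderate_variances(s2, df)
        df_total = df + (d0 if np.isfinite(d0) else 1e6)
    else:
        s2_post, df_total = s2, df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[:, ci] / (np.sqrt(s2_post) * se_unit)
    p_raw = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "emf": table.values.index,
            "emf_mz": table.emf_mz.values,
            "category": table.category.values,
            "coef_log2": B[:, ci],
            "t": t,
            "p_raw": p_raw,
            "significant": p_raw <= config.sig_threshold,
        }
    ).set_index("emf")
    return out


def compute_fold_change(
    table: EMFIntensityTable,
    metas: list[SampleMeta],
    config: StatsConfig = StatsConfig(),
) -> pd.DataFrame:
    """Fold change per EMF: mean(case) / mean(control) on the linear scale
    (ratio of averages), log2 applied afterwards.  Set
    ``config.linear_fold_change=False`` for the difference-of-log2-means
    alternative."""
    cond = {m.sample_id: m.condition for m in metas}
    cols = list(table.values.columns)
    case_cols = [c for c in cols if cond[c] == "case"]
    ctrl_cols = [c for c in cols if cond[c] == "control"]
    if not case_cols or not ctrl_cols:
        raise ValueError("both conditions must be present")
    if config.linear_fold_change:
        linear = 2.0**table.values
        fc = linear[case_cols].mean(axis=1) / linear[ctrl_cols].mean(axis=1)
        log2_fc = np.log2(fc)
    else:
        log2_fc = table.values[case_cols].mean(axis=1) - table.values[ctrl_cols].mean(axis=1)
        fc = 2.0**log2_fc
    return pd.DataFrame(
        {
            "emf_mz": table.emf_mz,
            "category": table.category,
            "fold_change": fc,
            "log2_fc": log2_fc,
        }
    )


def category_binomial(
    fold_changes: pd.DataFrame, config: StatsConfig = StatsConfig()
) -> pd.DataFrame:
    """Exact sign-binomial enrichment per lipid category.

    EMFs with log2 fold change > 0 count positive, <= 0 negative; the
    two-sided exact binomial test against a 50/50 null is Bonferroni-adjusted
    over the categories tested.  Rows with category "multiple", NOT_LIPID or
    NOT_CATEGORIZED must be removed beforehand (they are dropped here too).
    """
    kept = fold_changes[~fold_changes.category.isin(EXCLUDED_CATEGORIES)]
    cats = sorted(kept.category.unique())
    rows = []
    for cat in cats:
        sub = kept[kept.category == cat]
        n_pos = int((sub.log2_fc > 0).sum())
        n_neg = int((sub.log2_fc <= 0).sum())
        if n_pos + n_neg == 0:
            continue
        p = stats.binomtest(n_pos, n_pos + n_neg, config.null_prob).pvalue
        rows.append({"category": cat, "n_pos": n_pos, "n_neg": n_neg, "p_raw": p})
    df = pd.DataFrame(rows, columns=["category", "n_pos", "n_neg", "p_raw"])
    k = len(df)
    df["p_adj"] = np.minimum(1.0, df.p_raw * k)
    return df.set_index("category")


def weighted_pairwise_correlation(table: EMFIntensityTable) -> pd.DataFrame:
    """Information-weighted Pearson correlation between EMFs.

    r is computed over samples where both EMFs are observed (not imputed); the
    reported value is r * IC * ICon with IC = both-present / n and ICon =
    (both-present + both-missing) / n.  Pairs with < 3 co-present samples are
    NaN; the diagonal is exactly 1.
    """
    V = table.values.values
    present = ~table.imputed.values
    m, n = V.shape
    if n < 3:
        raise ValueError("need >= 3 samples for correlations")
    out = np.full((m, m), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(m):
        for j in range(i + 1, m):
            both = present[i] & present[j]
            nboth = int(both.sum())
            if nboth < 3:
                continue
            x, y = V[i, both], V[j, both]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            ic = nboth / n
            icon = (nboth + int((~present[i] & ~present[j]).sum())) / n
            out[i, j] = out[j, i] = r * ic * icon
    idx = table.values.index
    return pd.DataFrame(out, index=idx, columns=idx)
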