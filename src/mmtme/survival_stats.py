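"""Outcome analysis: Kaplan-Meier restricted means, log-rank tests,
quartile hazard ratios, lasso and stepwise Cox models, permutation-tested
survival trees, rank-test differential analysis, and contingency tests.

Cox ties use the Efron approximation throughout.  The survival tree is a
conditional-inference procedure: at each node the maximally selected
log-rank statistic over feature deciles is computed per feature, its
significance assessed by permutation of feature values with Bonferroni
correction across features, and the node splits only when the adjusted
permutation p-value passes the configured cutoff.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from statsmodels.stats.multitest import multipletests

from .io_config import PipelineConfig, ValidationError


def _check_surv(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape or len(t) == 0:
        raise ValidationError("times and events must be equal-length non-empty vectors")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValidationError("times must be finite and non-negative")
    return t, e


# ---------------------------------------------------------------------------
# Kaplan-Meier with restricted mean
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    event_times: np.ndarray
    survival_probabilities: np.ndarray
    restricted_mean: float
    restricted_mean_se: float
    horizon: float
    n: int
    n_events: int


def km_restricted_mean(times, events, horizon: Optional[float] = None) -> SurvivalFit:
    """Product-limit estimate with restricted mean +/- 1 SE.

    The restricted mean is the area under the KM curve up to ``horizon``
    (default: the largest observed time); its SE comes from the standard
    Greenwood-based area formula.
    """
    t, e = _check_surv(times, events)
    if horizon is None:
        horizon = float(t.max())
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy()
    surv = sf.iloc[:, 0].to_numpy()
    # area under the step function up to the horizon
    keep = grid <= horizon
    ts = np.concatenate([grid[keep], [horizon]])
    ss = surv[keep]
    seg_areas = ss * np.diff(ts)
    rmst = float(seg_areas.sum())
    # Greenwood-based variance: sum over event times of A(t_i)^2 d/(r(r-d)),
    # A(t_i) = area under the curve from t_i to the horizon
    tail_area = np.concatenate([np.cumsum(seg_areas[::-1])[::-1], [0.0]])
    ev = kmf.event_table
    ev = ev[(ev["observed"] > 0) & (ev.index <= horizon)]
    var = 0.0
    for ti, row in ev.iterrows():
        d, r = float(row["observed"]), float(row["at_risk"])
        if r - d <= 0:
            continue
        i = int(np.searchsorted(ts, ti))
        var += tail_area[i] ** 2 * d / (r * (r - d))
    return SurvivalFit(
        event_times=grid,
        survival_probabilities=surv,
        restricted_mean=rmst,
        restricted_mean_se=float(np.sqrt(max(var, 0.0))),
        horizon=float(horizon),
        n=len(t),
        n_events=int(e.sum()),
    )


def logrank_test(groups) -> dict:
    """Log-rank chi-square test across two or more groups."""
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    all_t, all_e, all_g = [], [], []
    for i, (times, events) in enumerate(groups):
        t, e = _check_surv(times, events)
        all_t.append(t)
        all_e.append(e)
        all_g.append(np.full(len(t), i))
    res = multivariate_logrank_test(
        np.concatenate(all_t), np.concatenate(all_g), np.concatenate(all_e)
    )
    return {
        "chi2": float(res.test_statistic),
        "df": len(groups) - 1,
        "p": float(res.p_value),
    }


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------


@dataclass
class CoxModel:
    features: list
    coefficients: np.ndarray       # log hazard ratios
    ci_95: np.ndarray              # (lo, hi) per feature on the log-HR scale
    p_values: np.ndarray
    penalty: float = 0.0
    tie_method: str = "efron"
    trace: list = field(default_factory=list)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)


def _fit_cox(df: pd.DataFrame, duration_col="time", event_col="event") -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def _cox_from_lifelines(cph: CoxPHFitter, penalty=0.0, trace=None) -> CoxModel:
    feats = list(cph.params_.index)
    ci = cph.confidence_intervals_.to_numpy()
    return CoxModel(
        features=feats,
        coefficients=cph.params_.to_numpy(),
        ci_95=ci,
        p_values=cph.summary["p"].to_numpy(),
        penalty=penalty,
        trace=trace or [],
    )


def quartile_hazard_ratio(feature, times, events) -> CoxModel:
    """Cox HR of the upper vs lowest quartile (middle half excluded).

    Quartile boundaries use ordinal (type-7) interpolation; values tied at a
    boundary go to the lower group.  Binary features pass straight through
    to a two-group Cox fit.
    """
    x = np.asarray(feature, dtype=float)
    t, e = _check_surv(times, events)
    if len(x) != len(t):
        raise ValidationError("feature and survival vectors differ in length")
    uniq = np.unique(x)
    if len(uniq) == 1:
        raise ValidationError("constant feature")
    if set(uniq).issubset({0.0, 1.0}):
        df = pd.DataFrame({"time": t, "event": e.astype(int), "high": x})
        return _cox_from_lifelines(_fit_cox(df))
    if len(x) < 20:
        raise ValidationError("quartile mode needs n >= 20")
    q1, q3 = np.quantile(x, [0.25, 0.75])  # numpy default = type-7 linear
    low = x <= q1
    high = x > q3
    keep = low | high
    df = pd.DataFrame(
        {"time": t[keep], "event": e[keep].astype(int), "high": high[keep].astype(float)}
    )
    return _cox_from_lifelines(_fit_cox(df))


def _efron_log_partial_likelihood(X, t, e, beta):
    """Efron-tie log partial likelihood (used for CV scoring of the path)."""
    eta = X @ beta
    order = np.argsort(-t)  # decreasing time
    t, e, eta = t[order], e[order], eta[order]
    exp_eta = np.exp(eta)
    ll = 0.0
    cum = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        cum += exp_eta[i:j].sum()
        d_idx = [k for k in range(i, j) if e[k]]
        d = len(d_idx)
        if d:
            tie_sum = exp_eta[d_idx].sum()
            ll += eta[d_idx].sum()
            for l in range(d):
                ll -= np.log(cum - (l / d) * tie_sum)
        i = j
    return ll


def cox_lasso(
    features: pd.DataFrame,
    times,
    events,
    cv_folds: int = 5,
    penalty: Optional[float] = None,
    seed: int = 0,
) -> CoxModel:
    """L1-penalized Cox regression with cross-validated penalty choice.

    Features are standardized internally; rows with missing values are
    dropped (count logged via warning).  ``penalty`` overrides the CV choice
    (0 gives the unpenalized fit).  Features with nonzero coefficients are
    the ones that "survive" the lasso.
    """
    X = features.copy()
    t, e = _check_surv(times, events)
    mask = ~X.isna().any(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} rows with missing features", RuntimeWarning)
        X, t, e = X[mask.to_numpy()], t[mask.to_numpy()], e[mask.to_numpy()]
    if e.sum() < 2:
        raise ValidationError("need at least 2 events")
    feats = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xv - mu) / sd

    if penalty == 0.0:
        df = pd.DataFrame(Xs, columns=feats)
        df["time"], df["event"] = t, e.astype(int)
        model = _cox_from_lifelines(_fit_cox(df))
        model.coefficients = model.coefficients / sd
        model.ci_95 = model.ci_95 / sd[:, None]
        return model

    y = np.array(
        [(bool(ev), tt) for ev, tt in zip(e, t)],
        dtype=[("event", "?"), ("time", "<f8")],
    )
    if penalty is not None:
        net = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[penalty], fit_baseline_model=False)
        net.fit(Xs, y)
        coef = net.coef_[:, 0]
        best_alpha = penalty
    else:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=30)
        path.fit(Xs, y)
        alphas = path.alphas_
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(t))
        folds = np.array_split(idx, cv_folds)
        scores = np.zeros(len(alphas))
        for f_idx in folds:
            tr = np.setdiff1d(idx, f_idx)
            if y[tr]["event"].sum() < 2 or y[f_idx]["event"].sum() < 1:
                continue
            m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas))
            m.fit(Xs[tr], y[tr])
            for a_i, alpha in enumerate(alphas):
                beta = m.coef_[:, a_i]
                scores[a_i] += _efron_log_partial_likelihood(Xs[f_idx], t[f_idx], e[f_idx], beta)
        best_alpha = float(alphas[int(np.argmax(scores))])
        refit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas))
        refit.fit(Xs, y)
        coef = refit.coef_[:, int(np.argmax(scores))]
    coef = coef / sd  # back to original feature scale
    return CoxModel(
        features=feats,
        coefficients=coef,
        ci_95=np.full((len(feats), 2), np.nan),
        p_values=np.full(len(feats), np.nan),
        penalty=float(best_alpha),
    )


def stepwise_cox(
    features: pd.DataFrame,
    times,
    events,
    always_keep=("age", "sex"),
    enter_p: float = 0.1,
    remove_p: float = 0.05,
) -> CoxModel:
    """Forward-backward stepwise Cox selection.

    Seeds with the feature of lowest univariate p-value; at each step the
    candidate whose nested-model likelihood-ratio test has the lowest
    p-value is added if p < ``enter_p``, then any non-protected feature
    whose coefficient test gives p > ``remove_p`` is removed.  Protected
    (``always_keep``) features stay regardless.  Stops when no candidate can
    be added, or when a model state repeats (cycle guard).
    """
    X = features.copy()
    t, e = _check_surv(times, events)
    mask = ~X.isna().any(axis=1)
    if (~mask).any():
        warnings.warn(
            f"dropping {int((~mask).sum())} rows with missing features", RuntimeWarning
        )
        X, t, e = X[mask.to_numpy()], t[mask.to_numpy()], e[mask.to_numpy()]
    feats = list(X.columns)
    protected = [f for f in always_keep if f in feats]
    candidates = [f for f in feats if f not in protected]

    def fit(sel):
        df = X[sel].copy()
        df["time"], df["event"] = t, e.astype(int)
        return _fit_cox(df)

    trace = []
    # univariate seeding
    uni_p = {}
    for f in candidates:
        try:
            uni_p[f] = float(fit([f]).summary["p"].iloc[0])
        except Exception:
            uni_p[f] = 1.0
    seed_feat = min(uni_p, key=lambda f: (uni_p[f], candidates.index(f)))
    selected = protected + [seed_feat]
    trace.append(("seed", seed_feat, uni_p[seed_feat]))

    seen_states = {frozenset(selected)}
    while True:
        base_fit = fit(selected)
        base_ll = base_fit.log_likelihood_
        # candidate scan: nested-model LR test
        best_f, best_p = None, np.inf
        for f in candidates:
            if f in selected:
                continue
            try:
                cand_fit = fit(selected + [f])
            except Exception:
                continue
            lr = 2 * (cand_fit.log_likelihood_ - base_ll)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if p < best_p:
                best_f, best_p = f, p
        if best_f is None or best_p >= enter_p:
            break
        selected = selected + [best_f]
        trace.append(("add", best_f, best_p))
        # backward pass: coefficient tests
        while True:
            m = fit(selected)
            pvals = m.summary["p"]
            removable = [
                f for f in selected if f not in protected and pvals[f] > remove_p
            ]
            if not removable:
                break
            worst = max(removable, key=lambda f: pvals[f])
            selected = [f for f in selected if f != worst]
            trace.append(("remove", worst, float(pvals[worst])))
        state = frozenset(selected)
        if state in seen_states:
            warnings.warn("stepwise selection revisited a model state; stopping",
                          RuntimeWarning)
            break
        seen_states.add(state)
    final = fit(selected)
    return _cox_from_lifelines(final, trace=trace)


# ---------------------------------------------------------------------------
# Conditional-inference survival tree
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    n: int
    n_events: int
    restricted_mean: float
    split_feature: Optional[str] = None
    split_threshold: Optional[float] = None
    permutation_p: Optional[float] = None
    left: Optional["TreeNode"] = None    # feature <= threshold
    right: Optional["TreeNode"] = None   # feature > threshold

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()


@dataclass
class SurvivalTree:
    root: TreeNode
    alpha: float
    n_permutations: int

    def split_sequence(self) -> list:
        """Split features in preorder (node, then its splittable children)."""
        seq = []

        def walk(node):
            if node.is_leaf:
                return
            seq.append(node.split_feature)
            walk(node.left)
            walk(node.right)

        walk(self.root)
        return seq

    def path_splits(self) -> list:
        """Split features along the remaining-population chain.

        After each split the still-unstratified patients sit on the
        low-value (<= threshold) side of a risk flag; following left
        children yields the stratification chain a clinician would read off
        the tree (flag, then next flag among the rest, and so on).
        """
        seq = []
        node = self.root
        while not node.is_leaf:
            seq.append(node.split_feature)
            node = node.left
        return seq


def _logrank_scores(t, e):
    """Log-rank (Savage) scores: event indicator minus Nelson-Aalen at t_i."""
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    n = len(ts)
    scores = np.zeros(n)
    cumhaz = 0.0
    i = 0
    at_risk = n
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d = es[i:j].sum()
        if d:
            cumhaz += d / at_risk
        scores[order[i:j]] = es[i:j] - cumhaz
        at_risk -= j - i
        i = j
    return scores


def _max_sel_stat(a_centered, ss, G):
    """Chi-square of the maximally selected linear rank statistic.

    ``G``: n x T indicator matrix (feature > threshold); returns the per-
    threshold chi2 vector for scores ``a_centered`` (already mean-centered).
    """
    n = len(a_centered)
    n1 = G.sum(axis=0)
    var = n1 * (n - n1) / (n * (n - 1)) * ss
    U = a_centered @ G
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, U ** 2 / var, 0.0)
    return chi2


def survival_tree(
    features: pd.DataFrame,
    times,
    events,
    alpha: float = 0.01,
    n_permutations: int = 10_000,
    min_node: int = 20,
    seed: int = 0,
) -> SurvivalTree:
    """Recursive partitioning with permutation-tested log-rank splits.

    Candidate thresholds are the feature deciles; the node-level p-value of
    the best feature comes from permuting feature values (Bonferroni
    corrected across features) and the node splits only when the adjusted
    p <= alpha.  Leaves report restricted mean survival on the shared
    root-level horizon so they are comparable.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    X = features.copy()
    t, e = _check_surv(times, events)
    if len(X) != len(t):
        raise ValidationError("features and survival vectors differ in length")
    rng = np.random.default_rng(seed)
    horizon = float(t.max())
    feat_names = list(X.columns)
    Xv = X.to_numpy(dtype=float)

    def node_fit(idx):
        fit = km_restricted_mean(t[idx], e[idx], horizon=horizon)
        return TreeNode(n=len(idx), n_events=int(e[idx].sum()),
                        restricted_mean=fit.restricted_mean)

    def build(idx):
        node = node_fit(idx)
        if len(idx) < 2 * min_node or e[idx].sum() < 2:
            return node
        a = _logrank_scores(t[idx], e[idx])
        ac = a - a.mean()
        ss = (ac ** 2).sum()
        if ss == 0:
            return node
        perms = np.empty((n_permutations, len(idx)))
        for p_i in range(n_permutations):
            perms[p_i] = ac[rng.permutation(len(idx))]
        best = None  # (p, -stat, feature, threshold)
        for f_i, f in enumerate(feat_names):
            x = Xv[idx, f_i]
            qs = np.unique(np.quantile(x, np.arange(0.1, 1.0, 0.1)))
            G = np.column_stack([(x > q) for q in qs]).astype(float)
            valid = (G.sum(axis=0) >= min_node) & (len(idx) - G.sum(axis=0) >= min_node)
            if not valid.any():
                continue
            G = G[:, valid]
            qs = qs[valid]
            obs = _max_sel_stat(ac, ss, G)
            obs_max = obs.max()
            thr = float(qs[int(np.argmax(obs))])
            perm_max = _max_sel_stat_batch(perms, ss, G)
            p = (1 + (perm_max >= obs_max).sum()) / (n_permutations + 1)
            # ties at the permutation floor are broken by the statistic
            # standardized against its own permutation distribution, which
            # removes the maximal-selection advantage of many-threshold
            # features over binary ones
            z = (obs_max - perm_max.mean()) / max(perm_max.std(), 1e-12)
            if best is None or (p, -z) < (best[0], best[1]):
                best = (p, -z, f, thr, f_i)
        if best is None:
            return node
        p_adj = min(1.0, best[0] * len(feat_names))
        if p_adj > alpha:
            return node
        _, _, f, thr, f_i = best
        node.split_feature = f
        node.split_threshold = thr
        node.permutation_p = p_adj
        left_idx = idx[Xv[idx, f_i] <= thr]
        right_idx = idx[Xv[idx, f_i] > thr]
        node.left = build(left_idx)
        node.right = build(right_idx)
        return node

    root = build(np.arange(len(t)))
    return SurvivalTree(root=root, alpha=alpha, n_permutations=n_permutations)


def _max_sel_stat_batch(perms, ss, G):
    n = perms.shape[1]
    n1 = G.sum(axis=0)
    var = n1 * (n - n1) / (n * (n - 1)) * ss
    U = perms @ G
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, U ** 2 / var, 0.0)
    return chi2.max(axis=1)


# ---------------------------------------------------------------------------
# Rank-test differential analysis
# ---------------------------------------------------------------------------


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # per feature: log2_fold_change, p_value, fdr, passes

    def passing(self) -> list:
        return list(self.table.index[self.table["passes"]])


def wilcoxon_de(
    matrix: pd.DataFrame,
    group_labels,
    paired: bool = False,
    fc_filter: bool = True,
    fdr_threshold: float = 0.05,
    abs_log2fc_threshold: float = 0.66,
) -> DifferentialResult:
    """Per-feature exact rank test between two groups with BH correction.

    Rank-sum for unpaired groups, signed-rank for paired (the field often
    labels both "Wilcoxon signed-rank").  Fold change is log2 of linear
    group means with pseudo-count 1.  ``passes`` requires fdr <= threshold
    and, when ``fc_filter``, |log2FC| > ``abs_log2fc_threshold``.
    """
    labels = pd.Series(group_labels)
    if len(labels) != matrix.shape[1]:
        raise ValidationError("one group label per sample column is required")
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValidationError(f"exactly 2 groups required, got {uniq}")
    g1 = matrix.loc[:, (labels == uniq[0]).to_numpy()]
    g2 = matrix.loc[:, (labels == uniq[1]).to_numpy()]
    if g1.shape[1] < 3 or g2.shape[1] < 3:
        raise ValidationError("each group needs n >= 3")
    if paired and g1.shape[1] != g2.shape[1]:
        raise ValidationError("paired test requires equal group sizes")
    ps = np.ones(matrix.shape[0])
    for i in range(matrix.shape[0]):
        x, y = g1.iloc[i].to_numpy(), g2.iloc[i].to_numpy()
        if paired:
            d = x - y
            if np.all(d == 0):
                ps[i] = 1.0
            else:
                ps[i] = stats.wilcoxon(x, y).pvalue
        else:
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                ps[i] = 1.0
            else:
                ps[i] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    log2fc = np.log2(g1.mean(axis=1) + 1) - np.log2(g2.mean(axis=1) + 1)
    fdr = multipletests(ps, method="fdr_bh")[1]
    passes = fdr <= fdr_threshold
    if fc_filter:
        passes = passes & (np.abs(log2fc) > abs_log2fc_threshold)
    table = pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": ps,
            "fdr": fdr,
            "passes": passes,
        },
        index=matrix.index,
    )
    return DifferentialResult(table)


def relapse_comparison(
    cell_props,
    clinical,
    config: Optional[PipelineConfig] = None,
) -> DifferentialResult:
    """Compare cell-type estimates near relapse vs complete remission.

    The relapse window is the configured span around the relapse date
    (default 180 days before to 30 days after); pretreatment (baseline)
    samples are excluded from the window.  Unpaired rank tests, no
    fold-change filter; the result table carries both FDR tiers (0.20 and
    0.05).
    """
    config = config or PipelineConfig()
    before = config.relapse_window_before_days
    after = config.relapse_window_after_days
    window, remission = [], []
    for r in clinical:
        if r.sample_id not in cell_props.percentages.index:
            continue
        off = r.relapse_date_offset_days
        in_window = (
            off is not None
            and -after <= off <= before
            and r.timepoint != "pretreatment"
        )
        if in_window:
            window.append(r.sample_id)
        elif r.complete_remission:
            remission.append(r.sample_id)
    if not window or not remission:
        raise ValidationError(
            f"empty comparison sets: {len(window)} relapse-window, "
            f"{len(remission)} remission samples"
        )
    mat = cell_props.percentages.loc[window + remission].T
    labels = ["relapse"] * len(window) + ["remission"] * len(remission)
    res = wilcoxon_de(
        mat, labels, paired=False, fc_filter=False, fdr_threshold=0.05
    )
    res.table["passes_fdr20"] = res.table["fdr"] <= 0.20
    res.table["passes_fdr05"] = res.table["fdr"] <= 0.05
    return res


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------


def chisq_independence(table, statistic: str = "pearson") -> dict:
    """Chi-square independence test without continuity correction.

    ``statistic`` selects Pearson's X^2 (default) or the likelihood-ratio
    G^2 ("log-likelihood").  A warning flag is set when any expected count
    is below 5 (the classical sample-size caveat).
    """
    m = np.asarray(table, dtype=float)
    if m.ndim != 2:
        raise ValidationError("table must be 2-D")
    if (m < 0).any() or not np.allclose(m, np.round(m)):
        raise ValidationError("table entries must be non-negative integers")
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        raise ValidationError("all row and column sums must be positive")
    lam = {"pearson": "pearson", "log-likelihood": "log-likelihood"}[statistic]
    chi2, p, df, expected = stats.chi2_contingency(m, correction=False, lambda_=lam)
    return {
        "chi2": float(chi2),
        "df": int(df),
        "p": float(p),
        "expected": expected,
        "low_expected_warning": bool((expected < 5).any()),
    }


def fisher_exact(table) -> dict:
    """Two-sided Fisher exact test with the conditional MLE odds ratio."""
    m = np.asarray(table, dtype=float)
    if m.shape != (2, 2):
        raise ValidationError("Fisher exact test requires a 2x2 table")
    if (m < 0).any() or not np.allclose(m, np.round(m)):
        raise ValidationError("table entries must be non-negative integers")
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        raise ValidationError("both margins must be positive")
    m = m.astype(int)
    _, p = stats.fisher_exact(m, alternative="two-sided")
    odds = stats.contingency.odds_ratio(m, kind="conditional").statistic
    return {"p_two_sided": float(p), "odds_ratio": float(odds)}


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values must be a non-empty 1-D vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
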