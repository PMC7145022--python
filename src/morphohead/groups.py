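"""Allometry, MANOVA on allometric trajectories, CVA ordination and
cross-validated discriminant classification.

Allometry — the dependence of shape on size — is quantified by multivariate
regression of tangent-space shape coordinates on centroid size; the
predicted sum of squares as a percent of the total is the strength of
allometry, and its significance comes from permuting sizes against shapes.
Whether groups share an allometric trajectory is tested with nested MANOVAs
on retained PC scores: Wilks' lambda of the group x size interaction (slope
differences) in the full model, and of the group effect (intercepts) after
dropping the interaction, with Rao's F approximation.

CVA finds the axes maximizing between-group relative to within-group
variance; classification uses a linear discriminant with pooled covariance
on retained PC scores, scored by leave-one-out cross-validation.
Mahalanobis machinery exists inside the CVA eigenproblem but no Mahalanobis
distances are reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .procrustes import ShapeSpace

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

@dataclass
class AllometryResult:
    percent_predicted: float
    p_value: float
    coefficients: np.ndarray      # shape-dimension slope vector (per unit CS)
    residual_shapes: np.ndarray   # (N, 3K), residuals + mean shape


def regress_shape_on_size(
    shape_space: ShapeSpace,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> AllometryResult:
    """Multivariate regression of tangent shape coordinates on centroid size."""
    n = shape_space.n_specimens
    if n < 5:
        raise ValueError("allometric regression needs at least 5 specimens")
    cs = shape_space.centroid_sizes.astype(float)
    if np.ptp(cs) <= 0:
        raise ValueError("centroid size is constant: slope undefined")
    y = shape_space.tangent_coordinates()
    ymean = y.mean(axis=0)
    yc = y - ymean
    xc = cs - cs.mean()
    sxx = float(xc @ xc)
    beta = (xc @ yc) / sxx
    ss_total = float((yc**2).sum())
    ss_pred = float((beta**2).sum() * sxx)
    percent = 100.0 * ss_pred / ss_total

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    # vectorized permutation null: ss_pred = ||x_perm^T Yc||^2 / sxx
    perms = np.stack([rng.permutation(xc) for _ in range(n_perm)])
    cross = perms @ yc  # (n_perm, 3K)
    null_ss = (cross**2).sum(axis=1) / sxx
    p = (int((null_ss >= ss_pred - 1e-12 * ss_total).sum()) + 1) / (n_perm + 1)

    residual = yc - np.outer(xc, beta) + ymean
    return AllometryResult(percent_predicted=percent, p_value=p,
                           coefficients=beta, residual_shapes=residual)


def pooled_within_group_size_correction(shape_space: ShapeSpace, labels) -> np.ndarray:
    """Size-corrected shapes from a pooled within-group regression on CS.

    A common slope is estimated on group-centered shape and size data;
    returned shapes are the residuals with each group's mean added back.
    """
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    y = shape_space.tangent_coordinates()
    cs = shape_space.centroid_sizes.astype(float)
    yc = np.empty_like(y)
    xc = np.empty_like(cs)
    used = np.zeros(len(cs), bool)
    for g in groups:
        m = labels == g
        if m.sum() < 2:
            warnings.warn(f"group {g!r} has a single member; excluded from slope estimation",
                          stacklevel=2)
            yc[m], xc[m] = 0.0, 0.0
            continue
        yc[m] = y[m] - y[m].mean(axis=0)
        xc[m] = cs[m] - cs[m].mean()
        used[m] = True
    sxx = float(xc[used] @ xc[used])
    if sxx <= 0:
        raise ValueError("no within-group size variation")
    slope = (xc[used] @ yc[used]) / sxx
    return y - np.outer(xc, slope)


# ---------------------------------------------------------------------------
# MANOVA on allometric trajectories
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    table: pd.DataFrame  # rows: <factor> x CS (slopes), <factor> (intercepts)


def wilks_rao(lambda_: float, p: int, h: int, v: float) -> tuple[float, float, float, float]:
    """Rao's F approximation for Wilks' lambda.

    ``p`` response variables, ``h`` hypothesis degrees of freedom, ``v``
    error degrees of freedom.  Returns (df_num, df_den, F, p_value); exact
    when min(p, h) <= 2.
    """
    ph = p * h
    denom = p**2 + h**2 - 5
    t = np.sqrt((p**2 * h**2 - 4) / denom) if denom > 0 else 1.0
    w = v - (p - h + 1) / 2.0
    df1 = ph
    df2 = w * t - (ph - 2) / 2.0
    lam_t = lambda_ ** (1.0 / t)
    f = (1 - lam_t) / lam_t * df2 / df1
    return df1, df2, f, float(sps.f.sf(f, df1, df2))


def _design(labels: np.ndarray, cs: np.ndarray, interaction: bool, group_effect: bool):
    cols = [np.ones(len(cs))]
    groups = sorted(set(labels))
    dummies = [(labels == g).astype(float) for g in groups[1:]]
    if group_effect:
        cols += dummies
    csc = cs - cs.mean()
    cols.append(csc)
    if interaction:
        cols += [d * csc for d in dummies]
    return np.column_stack(cols)


def _wilks_nested(y: np.ndarray, x_full: np.ndarray, x_reduced: np.ndarray):
    def resid(x):
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        return y - x @ coef
    e_full = resid(x_full)
    e_red = resid(x_reduced)
    e = e_full.T @ e_full
    h = e_red.T @ e_red - e
    sign_e, logdet_e = np.linalg.slogdet(e)
    sign_eh, logdet_eh = np.linalg.slogdet(e + h)
    if sign_e <= 0 or sign_eh <= 0:
        raise ValueError("singular error matrix: too many response variables for N; "
                         "lower the PC variance cutoff or pass a smaller score count")
    lam = float(np.exp(logdet_e - logdet_eh))
    return min(max(lam, 0.0), 1.0), np.linalg.matrix_rank(x_full)


def manova_allometry(pc_scores: np.ndarray, labels, cs) -> ManovaResult:
    """Slope and intercept tests of group allometric trajectories.

    Full model: group + CS + group x CS; the interaction's Wilks' lambda
    tests slope differences.  Reduced model without the interaction: the
    group effect's Wilks' lambda tests intercept differences.
    """
    y = np.asarray(pc_scores, float)
    labels = np.asarray(labels)
    cs = np.asarray(cs, float)
    n, q = y.shape
    groups = sorted(set(labels))
    g = len(groups)
    if q >= n - 2 * g:
        raise ValueError(f"{q} response variables leave no residual degrees of freedom "
                         f"for N={n}, {g} groups; use a smaller variance cutoff")
    y = y - y.mean(axis=0)

    rows = []
    # slopes: full vs no-interaction
    x_full = _design(labels, cs, interaction=True, group_effect=True)
    x_noint = _design(labels, cs, interaction=False, group_effect=True)
    lam, rank_full = _wilks_nested(y, x_full, x_noint)
    df1, df2, f, p = wilks_rao(lam, q, g - 1, n - rank_full)
    rows.append({"effect": "group x CS", "wilks": lam, "df_num": df1, "df_den": df2,
                 "F": f, "p": p})
    # intercepts: no-interaction vs CS-only
    x_csonly = _design(labels, cs, interaction=False, group_effect=False)
    lam2, rank_noint = _wilks_nested(y, x_noint, x_csonly)
    df1b, df2b, fb, pb = wilks_rao(lam2, q, g - 1, n - rank_noint)
    rows.append({"effect": "group", "wilks": lam2, "df_num": df1b, "df_den": df2b,
                 "F": fb, "p": pb})
    return ManovaResult(pd.DataFrame(rows).set_index("effect"))


# ---------------------------------------------------------------------------
# CVA and discriminant classification
# ---------------------------------------------------------------------------

@dataclass
class CVAResult:
    scores: np.ndarray        # (N, n_axes) canonical variate scores
    axes: np.ndarray          # (n_features, n_axes)
    eigenvalues: np.ndarray   # between/within variance ratios per axis


def cva(x: np.ndarray, labels) -> CVAResult:
    """Canonical variate analysis: eigenvectors of within^-1 x between scatter."""
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("CVA needs at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    xc = x - x.mean(axis=0)
    n, p = xc.shape
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for g in groups:
        m = labels == g
        gm = xc[m].mean(axis=0)
        dev = xc[m] - gm
        w += dev.T @ dev
        b += m.sum() * np.outer(gm, gm)
    # reduce dimension first if the within-scatter is singular; the usable
    # dimension is bounded by the within rank, n - number of groups
    basis = np.eye(p)
    if np.linalg.matrix_rank(w) < p:
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(evals)[::-1]
        n_keep = min(int((evals > evals.max() * 1e-10).sum()), n - len(groups))
        basis = evecs[:, order[:n_keep]]
        log.info("CVA: within-group scatter singular; reduced to %d PCs", n_keep)
        w = basis.T @ w @ basis
        b = basis.T @ b @ basis
    evals, evecs = linalg.eigh(b, w)
    order = np.argsort(evals)[::-1][: len(groups) - 1]
    axes = basis @ evecs[:, order]
    return CVAResult(scores=xc @ axes, axes=axes, eigenvalues=evals[order])


@dataclass
class ClassificationResult:
    confusion_row_pct: pd.DataFrame
    overall_accuracy_pct: float
    per_group_accuracy_pct: pd.Series
    discriminant_scores: np.ndarray
    wilks_lambda: float
    wilks_f: float
    wilks_p: float


def discriminant_classify(scores: np.ndarray, labels) -> ClassificationResult:
    """Leave-one-out linear discriminant classification on PC scores.

    Pooled-covariance LDA; the confusion matrix is row-percent by true group.
    Function significance is Wilks' lambda of the canonical eigenvalues with
    Rao's F.
    """
    x = np.asarray(scores, float)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    counts = {g: int((labels == g).sum()) for g in groups}
    if min(counts.values()) < 2:
        bad = min(counts, key=counts.get)
        raise ValueError(f"group {bad!r} has a single member; cannot cross-validate")
    n, q = x.shape
    q_max = min(counts.values()) - 1
    if q > q_max:
        log.info("shrinking feature count from %d to %d for covariance stability", q, q_max)
        x = x[:, :q_max]
        q = q_max

    predicted = np.empty(n, dtype=labels.dtype)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(x[train], labels[train])
        predicted[i] = clf.predict(x[i:i + 1])[0]

    conf = pd.crosstab(pd.Series(labels, name="true"), pd.Series(predicted, name="predicted"))
    conf = conf.reindex(index=groups, columns=groups, fill_value=0)
    row_pct = conf.div(conf.sum(axis=1), axis=0) * 100.0
    overall = 100.0 * float((predicted == labels).mean())
    per_group = pd.Series({g: row_pct.loc[g, g] for g in groups})

    cv = cva(x, labels)
    lam = float(np.prod(1.0 / (1.0 + cv.eigenvalues)))
    _, _, f, p = wilks_rao(lam, x.shape[1], len(groups) - 1, n - len(groups))
    full = LinearDiscriminantAnalysis(solver="svd").fit(x, labels)
    return ClassificationResult(confusion_row_pct=row_pct, overall_accuracy_pct=overall,
                                per_group_accuracy_pct=per_group,
                                discriminant_scores=full.transform(x) if len(groups) > 1 else x,
                                wilks_lambda=lam, wilks_f=f, wilks_p=p)
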