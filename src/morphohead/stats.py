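"""Shape statistics: relative warps, eigenvalue retention, hierarchical
Procrustes ANOVA with digitization error, and EDMA distance tables.

Principal components of tangent-space coordinates are the relative warps of
the sample.  How many to keep is decided by parallel analysis: observed
eigenvalues are compared with eigenvalues of data in which every coordinate
column was independently permuted across specimens, and components survive
while they exceed the chosen quantile of the permuted eigenvalues.

The Procrustes ANOVA partitions the total sum of squared Procrustes
deviations hierarchically — ethnicity, then sex, then age, then individual,
then digitization error (replicate digitizations of the same head) — with
degrees of freedom (levels - 1) * (3K - 7) for a main effect, 3K - 7 being
the dimension of shape space after superimposition of K landmarks in 3D.
F ratios follow the measurement-error ladder: each factor over the
individual stratum, individual over error.

EDMA compares forms through all (or selected) inter-anchor Euclidean
distances computed on group mean shapes; distances are reported in mm with
their base-10 logarithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry_io import SpecimenRecord
from .procrustes import ShapeSpace, gpa


def shape_dimension(n_landmarks: int) -> int:
    """Dimension of shape space for K landmarks in 3D: 3K - 7
    (translation 3, rotation 3, scale 1 removed by superimposition)."""
    return 3 * n_landmarks - 7


def main_effect_df(n_levels: int, n_landmarks: int) -> int:
    """Procrustes ANOVA degrees of freedom of a main effect."""
    return (n_levels - 1) * shape_dimension(n_landmarks)


# ---------------------------------------------------------------------------
# PCA / relative warps
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    components: np.ndarray          # (n_components, 3K) orthonormal loadings
    scores: np.ndarray              # (N, n_components), centered
    variance_fractions: np.ndarray  # percent of total variance per component
    retained_count: int
    mean: np.ndarray = field(default=None)

    def reconstruct(self) -> np.ndarray:
        """Back-project scores through the loadings (adds the mean back)."""
        return self.scores @ self.components + self.mean


def pca(shape_space: ShapeSpace, retained_count: int | None = None) -> PCAResult:
    """Relative warps: eigen-decomposition of the tangent-space covariance."""
    if shape_space.n_specimens < 3:
        raise ValueError("PCA needs at least 3 specimens")
    x = shape_space.tangent_coordinates()
    mean = x.mean(axis=0)
    xc = x - mean
    n = len(xc)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > eig[0] * 1e-12 if eig[0] > 0 else slice(0, 1)
    eig, u, s, vt = eig[keep], u[:, keep], s[keep], vt[keep]
    # deterministic signs: largest-magnitude loading of each component positive
    signs = np.sign(vt[np.arange(len(eig)), np.argmax(np.abs(vt), axis=1)])
    vt = vt * signs[:, None]
    scores = xc @ vt.T
    frac = 100.0 * eig / eig.sum()
    max_rank = min(n - 1, shape_dimension(shape_space.n_landmarks))
    if retained_count is None:
        retained_count = min(len(eig), max_rank)
    retained_count = min(retained_count, len(eig), max_rank)
    return PCAResult(eigenvalues=eig, components=vt, scores=scores,
                     variance_fractions=frac, retained_count=retained_count, mean=mean)


def parallel_analysis_retention(
    shape_space: ShapeSpace,
    n_random: int = 100,
    quantile: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> int:
    """Number of components whose eigenvalues beat column-permuted data.

    Each coordinate column is permuted independently across specimens
    ``n_random`` times; a component is retained while its observed eigenvalue
    exceeds the ``quantile`` of the permuted eigenvalues of the same rank
    (leading-run convention).
    """
    if n_random < 10:
        warnings.warn("parallel analysis with n_random < 10 is unreliable", stacklevel=2)
    x = shape_space.tangent_coordinates()
    xc = x - x.mean(axis=0)
    n = len(xc)
    observed = np.linalg.svd(xc, compute_uv=False) ** 2 / (n - 1)
    rng = np.random.default_rng(seed)
    rand_eigs = np.zeros((n_random, len(observed)))
    for r in range(n_random):
        perm = xc.copy()
        for j in range(perm.shape[1]):
            perm[:, j] = perm[rng.permutation(n), j]
        s = np.linalg.svd(perm, compute_uv=False) ** 2 / (n - 1)
        rand_eigs[r, :len(s)] = s[:len(observed)]
    threshold = np.quantile(rand_eigs, quantile, axis=0)
    retained = 0
    for lam, thr in zip(observed, threshold):
        if lam > thr:
            retained += 1
        else:
            break
    return retained


# ---------------------------------------------------------------------------
# Hierarchical Procrustes ANOVA
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesAnovaTable:
    table: pd.DataFrame  # rows: effects; columns: variance_pct, SS, MS, DF, F, p
    partition: str = "all"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()


def _dummy(values: np.ndarray) -> tuple[np.ndarray, int]:
    levels = sorted(set(values))
    cols = [np.asarray(values) == lv for lv in levels[1:]]
    mat = np.column_stack(cols).astype(float) if cols else np.empty((len(values), 0))
    return mat, len(levels)


def _partition_slice(partition: str, anchor_count: int, total: int) -> slice:
    if partition == "anchors":
        return slice(0, anchor_count)
    if partition == "semilandmarks":
        return slice(anchor_count, total)
    if partition == "all":
        return slice(0, total)
    raise ValueError("partition must be 'anchors', 'semilandmarks' or 'all'")


def procrustes_anova(
    configs: np.ndarray,
    records: list[SpecimenRecord],
    anchor_count: int,
    partition: str = "all",
) -> ProcrustesAnovaTable:
    """Goodall-type hierarchical Procrustes ANOVA with a digitization-error stratum.

    ``configs`` is (n_observations, K, 3) raw landmark data, one row per
    digitization (replicates included); ``records`` supplies the factors and
    the ``replicate_of`` links.  The chosen landmark ``partition`` is
    superimposed on its own before decomposition.  Factor order is fixed:
    ethnicity, sex, age, individual, error.
    """
    configs = np.asarray(configs, float)
    if len(records) != len(configs):
        raise ValueError("one metadata record per configuration required")
    sel = _partition_slice(partition, anchor_count, configs.shape[1])
    sub = configs[:, sel, :]
    k = sub.shape[1]
    space = gpa(sub, [r.id for r in records])
    y = space.aligned.reshape(len(records), -1)

    indiv = np.array([r.replicate_of or r.id for r in records])
    eth = np.array([r.ethnicity for r in records])
    sex = np.array([r.sex for r in records])
    age = np.array([r.age_class for r in records])
    for name, vals in (("ethnicity", eth), ("sex", sex), ("age", age)):
        if len(set(vals)) < 2:
            raise ValueError(f"factor {name} needs >= 2 levels")

    def rss(design_cols: list[np.ndarray]) -> float:
        x = np.column_stack([np.ones(len(y))] + design_cols)
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        return float(((y - x @ coef) ** 2).sum())

    d_eth, l_eth = _dummy(eth)
    d_sex, l_sex = _dummy(sex)
    d_age, l_age = _dummy(age)
    d_ind, n_ind = _dummy(indiv)

    rss0 = float(((y - y.mean(axis=0)) ** 2).sum())
    rss_e = rss([d_eth])
    rss_es = rss([d_eth, d_sex])
    rss_esa = rss([d_eth, d_sex, d_age])
    rss_ind = rss([d_ind])  # individual means absorb every factor above
    for lower, upper, name in ((rss_e, rss0, "ethnicity"), (rss_es, rss_e, "sex"),
                               (rss_esa, rss_es, "age")):
        if upper - lower < -1e-9 * max(rss0, 1.0):
            raise ValueError(f"factor {name} is confounded with a higher effect")

    ss = {
        "Ethnicity": rss0 - rss_e,
        "Sex": rss_e - rss_es,
        "Age": rss_es - rss_esa,
        "Individual": rss_esa - rss_ind,
        "Digitizing Error": rss_ind,
    }

    s = shape_dimension(k)
    n_obs = len(records)
    has_replicates = n_obs > n_ind
    df = {
        "Ethnicity": (l_eth - 1) * s,
        "Sex": (l_sex - 1) * s,
        "Age": (l_age - 1) * s,
        "Individual": (n_ind - 1 - (l_eth - 1) - (l_sex - 1) - (l_age - 1)) * s,
        "Digitizing Error": (n_obs - n_ind) * s,
    }
    effects = list(ss)
    if not has_replicates:
        warnings.warn("no replicate digitizations: error stratum omitted", stacklevel=2)
        effects = effects[:-1]

    total_ss = sum(ss[e] for e in effects)
    rows = []
    ms = {e: ss[e] / df[e] if df[e] > 0 else np.nan for e in effects}
    for e in effects:
        if e == "Digitizing Error":
            f_val, p = np.nan, np.nan
        elif e == "Individual":
            if has_replicates and df["Digitizing Error"] > 0:
                f_val = ms[e] / ms["Digitizing Error"]
                p = sps.f.sf(f_val, df[e], df["Digitizing Error"])
            else:
                f_val, p = np.nan, np.nan
        else:
            f_val = ms[e] / ms["Individual"]
            p = sps.f.sf(f_val, df[e], df["Individual"])
        rows.append({
            "effect": e,
            "variance_pct": 100.0 * ss[e] / total_ss,
            "SS": ss[e], "MS": ms[e], "DF": df[e], "F": f_val, "p": p,
        })
    rows.append({"effect": "Total", "variance_pct": 100.0, "SS": total_ss,
                 "MS": np.nan, "DF": sum(df[e] for e in effects), "F": np.nan, "p": np.nan})
    return ProcrustesAnovaTable(pd.DataFrame(rows).set_index("effect"), partition=partition)


# ---------------------------------------------------------------------------
# EDMA
# ---------------------------------------------------------------------------

@dataclass
class EDMAResult:
    table: pd.DataFrame  # columns: pair, distance_mm, log10_distance


#: the named inter-anchor distances of the anthropometric battery
NAMED_DISTANCES = [
    ("me", "op"), ("me", "n"), ("me", "gn"), ("tl", "tr"),
    ("enl", "enr"), ("exl", "exr"), ("n", "pr"), ("all", "alr"),
    ("chl", "chr"), ("ls", "li"), ("li", "gn"), ("tl", "gn"),
]


def edma_log_distances(
    mean_config: np.ndarray,
    labels: list[str],
    pairs="all",
) -> EDMAResult:
    """Inter-anchor Euclidean distances (mm) on a mean configuration.

    ``pairs`` is either ``"all"`` (every unordered anchor pair) or a list of
    label pairs.  Base-10 logs are reported alongside.
    """
    mean_config = np.asarray(mean_config, float)
    index = {lab: i for i, lab in enumerate(labels)}
    if isinstance(pairs, str) and pairs == "all":
        pairs = list(combinations(labels, 2))
    rows = []
    for a, b in pairs:
        if a not in index or b not in index:
            raise KeyError(f"unknown anchor label in pair ({a}, {b}); valid: {', '.join(labels)}")
        d = float(np.linalg.norm(mean_config[index[a]] - mean_config[index[b]]))
        rows.append({"pair": f"{a}-{b}", "distance_mm": d, "log10_distance": np.log10(d)})
    return EDMAResult(pd.DataFrame(rows))


def group_mean_forms(shape_space: ShapeSpace, labels) -> dict:
    """Mean *forms* per group: aligned mean shape rescaled by the group's mean
    centroid size, so EDMA distances come out in mm."""
    labels = np.asarray(labels)
    out = {}
    for g in sorted(set(labels)):
        mask = labels == g
        mean_shape = shape_space.aligned[mask].mean(axis=0)
        mean_shape = mean_shape - mean_shape.mean(axis=0)
        cs = float(shape_space.centroid_sizes[mask].mean())
        norm = np.sqrt((mean_shape**2).sum())
        out[g] = mean_shape / norm * cs
    return out
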