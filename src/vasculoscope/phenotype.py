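"""Vessel-niche classification, heterogeneity indices and ensemble analysis.

Perfused tumor vessels fall into four functional niches, using velocity
and oxygenation thresholds from the tumor-hemodynamics literature:

* Class 1 — hypoperfused and hypoxic (Vel < 50 µm/s and PO2 < 10 mmHg);
* Class 2 — hyperperfused and normoxic (Vel ≥ 50 µm/s and PO2 ≥ 10 mmHg);
* Class 3 — mixed (hypoperfused+normoxic or hyperperfused+hypoxic);
* Class 4 — functional shunts: velocity ≥ 2× the median, diameter ≥ 2×
  the median, length ≤ 0.5× the median (medians over the perfused vessels
  of the same network).  Shunt criteria are tested first because they can
  co-occur with Class 2's.

Heterogeneity across a tumor ensemble is summarized by the coefficient of
variation of each parameter, the Pearson correlation matrix between those
CVs, Mann–Whitney group comparisons, and UPGMA hierarchical clustering of
per-network median feature vectors (z-scored; cophenetic correlation
above 0.8 counts as a trustworthy dendrogram).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .hemodynamics import PERFUSION_FLOOR, HemodynamicState
from .oxygen import OxygenState

__all__ = [
    "ClassThresholds",
    "classify_vessels",
    "coefficient_of_variation",
    "cv_correlation_matrix",
    "derived_flow_metrics",
    "mean_path_length",
    "compare_groups",
    "cluster_networks",
    "ClusterResult",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassThresholds:
    """Thresholds of the four-niche classification."""

    velocity_um_s: float = 50.0
    po2_mmHg: float = 10.0
    shunt_velocity_multiple: float = 2.0
    shunt_diameter_multiple: float = 2.0
    shunt_length_factor: float = 0.5
    perfusion_floor_ul_s: float = PERFUSION_FLOOR

    def __post_init__(self):
        for f in ("velocity_um_s", "po2_mmHg", "shunt_velocity_multiple",
                  "shunt_diameter_multiple", "shunt_length_factor", "perfusion_floor_ul_s"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


def classify_vessels(
    hemo: HemodynamicState,
    oxy: OxygenState,
    diameters: np.ndarray,
    lengths: np.ndarray,
    thresholds: ClassThresholds = ClassThresholds(),
) -> np.ndarray:
    """Label every perfused segment 1–4 (0 for unperfused segments).

    Medians for the shunt criteria are computed over the perfused vessels
    of this network.  Shunts (Class 4) take precedence; then Class 1
    (slow and hypoxic), Class 2 (fast and normoxic), Class 3 otherwise.
    """
    vel_um_s = hemo.velocity * 1e3  # mm/s → µm/s
    po2 = oxy.segment_po2
    perfused = np.abs(hemo.flow) >= thresholds.perfusion_floor_ul_s
    if not perfused.any():
        raise ValueError("no perfused segments to classify")
    med_vel = float(np.median(vel_um_s[perfused]))
    med_d = float(np.median(np.asarray(diameters)[perfused]))
    med_l = float(np.median(np.asarray(lengths)[perfused]))

    labels = np.zeros(len(hemo.flow), dtype=int)
    shunt = (
        (vel_um_s >= thresholds.shunt_velocity_multiple * med_vel)
        & (np.asarray(diameters) >= thresholds.shunt_diameter_multiple * med_d)
        & (np.asarray(lengths) <= thresholds.shunt_length_factor * med_l)
    )
    slow = vel_um_s < thresholds.velocity_um_s
    hypoxic = po2 < thresholds.po2_mmHg
    labels[perfused & slow & hypoxic] = 1
    labels[perfused & ~slow & ~hypoxic] = 2
    labels[perfused & (slow ^ hypoxic)] = 3
    labels[perfused & shunt] = 4
    return labels


def coefficient_of_variation(values) -> float:
    """Sample standard deviation divided by the mean (needs n ≥ 2, mean ≠ 0)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(np.std(v, ddof=1) / mean)


def cv_correlation_matrix(cv_table: pd.DataFrame, alpha: float = 0.05):
    """Pairwise Pearson correlation of per-network CVs.

    ``cv_table``: one row per network, one column per parameter, no
    missing entries, at least 3 networks.  Returns (r, p, significant)
    DataFrames; constant columns yield NaN entries (undefined r).
    """
    if cv_table.isna().any().any():
        raise ValueError("CV table has missing entries")
    if len(cv_table) < 3:
        raise ValueError("need at least 3 networks for correlation")
    cols = list(cv_table.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = cv_table[cols[i]].to_numpy(float)
            y = cv_table[cols[j]].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    sig = (pdf < alpha) & np.isfinite(rdf)
    np.fill_diagonal(sig.values, False)
    return rdf, pdf, sig


def derived_flow_metrics(hemo: HemodynamicState) -> pd.DataFrame:
    """Per-segment velocity, shear stress and transit time plus perfusion flag.

    vstt is +inf on zero-flow segments; those are excluded from perfused
    statistics downstream.
    """
    return pd.DataFrame(
        {
            "segment_id": hemo.segment_ids,
            "velocity_mm_s": hemo.velocity,
            "wss_dyn_cm2": hemo.wall_shear_stress,
            "vstt_s": hemo.transit_time,
            "perfused": hemo.perfused,
        }
    )


def mean_path_length(flow, lengths) -> float:
    """Flow-weighted mean segment length MPL = ΣQL / ΣQ, µm."""
    q = np.abs(np.asarray(flow, dtype=float))
    length = np.asarray(lengths, dtype=float)
    if float(np.sum(q)) == 0.0:
        raise ValueError("mean path length undefined for an unperfused network")
    return float(np.sum(q * length) / np.sum(q))


def compare_groups(values_a, values_b, alpha: float = 0.05):
    """Two-sided Mann–Whitney U test between two networks/groups.

    Returns (U statistic, two-sided p, significant-at-alpha).  Fully tied
    degenerate data yields p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied; Mann-Whitney p set to 1", stacklevel=2)
        return float(a.size * b.size / 2.0), 1.0, False
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


@dataclass
class ClusterResult:
    """UPGMA clustering of per-network feature vectors."""

    linkage: np.ndarray
    labels: np.ndarray
    cophenetic: float
    feature_names: list[str] = field(default_factory=list)
    network_ids: list = field(default_factory=list)
    significant: bool = True  # cophenetic > 0.8


def cluster_networks(
    features: pd.DataFrame,
    feature_set: list[str] | None = None,
    n_clusters: int | None = 2,
    distance_threshold: float | None = None,
) -> ClusterResult:
    """UPGMA (average-linkage) clustering of networks on z-scored features.

    ``features``: one row per network (index = network id), numeric
    columns.  Features are z-scored before Euclidean distances because
    units are mixed.  Flat labels come from ``n_clusters`` (default 2) or
    a ``distance_threshold`` on the dendrogram.  The cophenetic
    correlation coefficient is reported and flagged when ≤ 0.8.
    """
    if feature_set is not None:
        features = features[list(feature_set)]
    if len(features) < 2:
        raise ValueError("need at least 2 networks to cluster")
    x = features.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant features carry no distance
    z = (x - mu) / sd
    d = pdist(z, metric="euclidean")
    if np.any(d == 0):
        log.info("duplicate feature rows found (zero pairwise distance)")
    link = hierarchy.linkage(d, method="average")
    coph, _ = hierarchy.cophenet(link, d)
    if distance_threshold is not None:
        labels = hierarchy.fcluster(link, t=distance_threshold, criterion="distance")
    else:
        labels = hierarchy.fcluster(link, t=n_clusters or 2, criterion="maxclust")
    coph = float(coph)
    if coph <= 0.8:
        log.warning("cophenetic coefficient %.3f <= 0.8: clustering unreliable", coph)
    return ClusterResult(
        linkage=link,
        labels=np.asarray(labels),
        cophenetic=coph,
        feature_names=list(features.columns),
        network_ids=list(features.index),
        significant=coph > 0.8,
    )
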