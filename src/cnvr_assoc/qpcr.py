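"""qPCR copy-number assignment: ratios -> diploid copy classes -> carriers.

Normalized TaqMan ratios (target locus over a reference locus and a pool
of control DNAs) sit near m/2 for a diploid copy number m.  The mean
ratio over the assays within the rearranged region is doubled to a naive
diploid copy estimate and samples are grouped by one-dimensional k-means
with centroids deterministically initialized at the theoretical ratios
1.0, 1.5, 2.0 and 2.5 (copy classes 2, 3, 4 and >4).  Because the qPCR
chemistry cannot resolve more than four copies reliably, any sample whose
naive estimate exceeds 4.5 copies is forced into the ">4" class.  A
carrier is any sample with three or more diploid copies.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

COPY_CLASSES = ("2", "3", "4", "gt4")
THEORETICAL_RATIOS = (1.0, 1.5, 2.0, 2.5)
GT4_NAIVE_CUTOFF = 4.5


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    assay_id: str
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError(f"{self.sample_id}/{self.assay_id}: ratio < 0")


@dataclass(frozen=True)
class CopyNumberAssignment:
    sample_id: str
    mean_ratio: float
    diploid_copies: str  # one of COPY_CLASSES
    carrier: bool


def normalize_to_diploid(
    measurements: Sequence[QpcrMeasurement] | pd.DataFrame,
) -> pd.DataFrame:
    """Average each sample's assay ratios and double to a naive copy number.

    Every sample must carry the same assay set; a missing assay is an
    error.  Returns a DataFrame with columns sample_id, mean_ratio,
    naive_copies, sorted by sample_id.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements[["sample_id", "assay_id", "ratio"]].copy()
    else:
        df = pd.DataFrame(
            [(m.sample_id, m.assay_id, m.ratio) for m in measurements],
            columns=["sample_id", "assay_id", "ratio"],
        )
    if df.empty:
        raise ValueError("no qPCR measurements supplied")
    if (df["ratio"] < 0).any():
        raise ValueError("negative qPCR ratio")
    assay_sets = df.groupby("sample_id")["assay_id"].agg(frozenset)
    full = frozenset(df["assay_id"].unique())
    incomplete = assay_sets[assay_sets != full]
    if not incomplete.empty:
        sid = incomplete.index[0]
        missing = sorted(full - incomplete.iloc[0])
        raise ValueError(f"sample {sid!r} is missing assay(s) {missing}")
    out = (
        df.groupby("sample_id", as_index=False)["ratio"]
        .mean()
        .rename(columns={"ratio": "mean_ratio"})
        .sort_values("sample_id", ignore_index=True)
    )
    out["naive_copies"] = 2.0 * out["mean_ratio"]
    return out


def assign_copy_classes(
    table: pd.DataFrame,
    k_max: int = 4,
    seed: int = 0,
) -> list[CopyNumberAssignment]:
    """Cluster mean ratios into diploid copy classes 2 / 3 / 4 / >4.

    One-dimensional k-means with centroids initialized at the theoretical
    ratios; only theoretical centroids that are nearest to at least one
    sample are retained, which fixes k and makes the assignment
    deterministic.  Clusters are labelled by the copy class of the
    theoretical ratio closest to their final centroid (ascending in the
    mean ratio), and samples with naive_copies > 4.5 are forced to ">4".
    With fewer samples than clusters the method falls back to
    nearest-theoretical-ratio assignment with a warning.
    """
    if not 1 <= k_max <= len(THEORETICAL_RATIOS):
        raise ValueError(f"k_max must be in [1, {len(THEORETICAL_RATIOS)}]")
    ratios = table["mean_ratio"].to_numpy(dtype=float)
    naive = (
        table["naive_copies"].to_numpy(dtype=float)
        if "naive_copies" in table
        else 2.0 * ratios
    )
    theory = np.asarray(THEORETICAL_RATIOS[:k_max])

    # retain only theoretical centroids that attract >=1 sample
    nearest = np.argmin(np.abs(ratios[:, None] - theory[None, :]), axis=1)
    retained = np.unique(nearest)
    k = len(retained)

    if len(ratios) < k:
        warnings.warn(
            "fewer samples than clusters; falling back to "
            "nearest-theoretical-ratio assignment",
            stacklevel=2,
        )
        labels = [COPY_CLASSES[i] for i in nearest]
    else:
        km = KMeans(
            n_clusters=k,
            init=theory[retained].reshape(-1, 1),
            n_init=1,
            random_state=seed,
        ).fit(ratios.reshape(-1, 1))
        centroids = km.cluster_centers_.ravel()
        order = np.argsort(centroids)
        class_of_cluster = {}
        used_classes = [int(np.argmin(np.abs(theory - centroids[j]))) for j in order]
        if len(set(used_classes)) < k:
            # centroid drift collapsed two labels: keep the retained
            # initial classes in ascending order instead
            used_classes = list(retained)
        for j, cls_idx in zip(order, used_classes):
            class_of_cluster[j] = COPY_CLASSES[cls_idx]
        labels = [class_of_cluster[j] for j in km.labels_]

    out = []
    for sid, ratio, nv, label in zip(table["sample_id"], ratios, naive, labels):
        if nv > GT4_NAIVE_CUTOFF:
            label = "gt4"
        out.append(
            CopyNumberAssignment(
                sample_id=str(sid),
                mean_ratio=float(ratio),
                diploid_copies=label,
                carrier=label != "2",
            )
        )
    return out


def carrier_concordance(
    assignments: Sequence[CopyNumberAssignment],
    confirmatory: pd.DataFrame,
) -> tuple[int, int, list[str]]:
    """Compare qPCR carrier status with a confirmatory assay.

    ``confirmatory`` needs columns sample_id and carrier.  Only samples
    present in both inputs are compared; returns (n_concordant,
    n_discordant, sorted discordant ids).
    """
    qpcr = {a.sample_id: a.carrier for a in assignments}
    conf = dict(
        zip(confirmatory["sample_id"].astype(str), confirmatory["carrier"].astype(bool))
    )
    shared = sorted(set(qpcr) & set(conf))
    discordant = [sid for sid in shared if qpcr[sid] != conf[sid]]
    return len(shared) - len(discordant), len(discordant), discordant
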