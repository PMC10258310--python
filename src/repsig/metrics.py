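"""Repertoire diversity, similarity and gene-usage features.

Clonotype abundances are summarized at two feature levels:

* **CDR3aa** — clones are identified by their CDR3 amino-acid sequence;
* **VDJ** — clones are identified by their (V, D, J) gene-segment
  combination, alleles stripped, empty D allowed for chains without D.

Diversity is richness (number of unique clone labels, S) and evenness
(normalized Shannon entropy, H / ln S — Pielou evenness); repertoire overlap
is the Morisita-Horn similarity index on abundances. Gene-segment usage is
exposed as per-sample frequency matrices with PCA / classical-MDS ordination.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RepertoireSample

logger = logging.getLogger(__name__)

LEVELS = ("CDR3aa", "VDJ")


class EmptyProfileError(ValueError):
    """Diversity/similarity is undefined on an empty abundance profile."""


@dataclass(slots=True)
class AbundanceProfile:
    """Clone label -> positive count at a chosen feature level."""

    level: str
    counts: dict[Hashable, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        return len(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True, slots=True)
class DiversityResult:
    richness: int
    shannon: float  # nats
    nsde: float  # in [0, 1]


@dataclass(frozen=True, slots=True)
class SimilarityResult:
    mhsi: float
    n_shared_labels: int


def collapse(sample: RepertoireSample, level: str = "CDR3aa") -> AbundanceProfile:
    """Aggregate a (filtered) sample into an abundance profile.

    CDR3aa level keys by the amino-acid sequence; VDJ level keys by the
    (v_call, d_call, j_call) tuple. Counts of clonotypes sharing a key are
    summed.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    counts: dict[Hashable, int] = {}
    for c in sample.clonotypes:
        key: Hashable = c.cdr3_aa if level == "CDR3aa" else (c.v_call, c.d_call, c.j_call)
        counts[key] = counts.get(key, 0) + c.count
    counts = {k: v for k, v in counts.items() if v > 0}
    if not counts:
        logger.warning("empty sample %s collapsed to empty profile", sample.sample_id)
    return AbundanceProfile(level=level, counts=counts)


def diversity(profile: AbundanceProfile) -> DiversityResult:
    """Richness S, Shannon entropy H (nats) and normalized entropy H/ln S.

    A single-clone repertoire has NSDE 0 by convention (maximal clonality).
    """
    if len(profile) == 0:
        raise EmptyProfileError("diversity is undefined on an empty profile")
    counts = np.asarray(list(profile.counts.values()), dtype=float)
    p = counts / counts.sum()
    shannon = float(-(p * np.log(p)).sum())
    s = len(counts)
    nsde = shannon / math.log(s) if s >= 2 else 0.0
    return DiversityResult(richness=s, shannon=shannon, nsde=nsde)


def morisita_horn(a: AbundanceProfile, b: AbundanceProfile) -> SimilarityResult:
    """Morisita-Horn similarity of two abundance profiles.

    With counts x_i, y_i of label i, totals X and Y, and Simpson-type
    concentrations d_x = sum(x_i^2)/X^2 and d_y = sum(y_i^2)/Y^2:

        MHSI = 2 * sum(x_i * y_i) / ((d_x + d_y) * X * Y)

    Bounded in [0, 1]; 1 for identical relative abundances; 0 iff the label
    sets are disjoint.
    """
    if a.level != b.level:
        raise ValueError(f"level mismatch: {a.level!r} vs {b.level!r}")
    if len(a) == 0 or len(b) == 0:
        raise EmptyProfileError("Morisita-Horn is undefined on an empty profile")
    X = a.total
    Y = b.total
    d_x = sum(v * v for v in a.counts.values()) / (X * X)
    d_y = sum(v * v for v in b.counts.values()) / (Y * Y)
    shared = a.counts.keys() & b.counts.keys()
    cross = sum(a.counts[k] * b.counts[k] for k in shared)
    mhsi = 2.0 * cross / ((d_x + d_y) * X * Y)
    return SimilarityResult(mhsi=float(mhsi), n_shared_labels=len(shared))


@dataclass(slots=True)
class UsageMatrix:
    """Per-sample gene-segment relative frequencies.

    ``frequencies`` is a DataFrame with one row per sample and one column per
    segment label (union over samples, absent segments 0); nonempty rows sum
    to 1. ``empty_samples`` lists the ids of all-zero rows.
    """

    segment: str
    frequencies: pd.DataFrame
    empty_samples: list[str] = field(default_factory=list)


_SEGMENTS = ("V", "J", "VDJ")


def usage_matrix(samples: Sequence[RepertoireSample], segment: str = "VDJ") -> UsageMatrix:
    """Count-weighted segment-usage frequencies across samples."""
    if segment not in _SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}; expected one of {_SEGMENTS}")
    rows: dict[str, dict[str, float]] = {}
    empty: list[str] = []
    for s in samples:
        acc: dict[str, float] = {}
        for c in s.clonotypes:
            if segment == "V":
                label = c.v_call
            elif segment == "J":
                label = c.j_call
            else:
                label = f"{c.v_call}|{c.d_call}|{c.j_call}"
            acc[label] = acc.get(label, 0.0) + c.count
        total = sum(acc.values())
        if total == 0:
            empty.append(s.sample_id)
            rows[s.sample_id] = {}
        else:
            rows[s.sample_id] = {k: v / total for k, v in acc.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    df = df.reindex(sorted(df.columns), axis=1)
    if empty:
        logger.warning("all-zero usage rows for samples: %s", empty)
    return UsageMatrix(segment=segment, frequencies=df, empty_samples=empty)


def _fix_signs_by(scores: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip axes so the largest-magnitude entry of ``reference`` is positive."""
    flips = np.ones(reference.shape[1])
    for j in range(reference.shape[1]):
        col = reference[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            flips[j] = -1.0
    return scores * flips, reference * flips


def pca_coordinates(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """PCA scores of column-centered (unscaled) frequency rows.

    Rows are compositional frequencies on a common scale, so no variance
    scaling is applied. Per-axis sign is fixed so the largest-magnitude
    loading is positive, making the output deterministic.
    """
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * sv[:n_components]
    loadings = Vt[:n_components].T
    scores, _ = _fix_signs_by(scores, loadings)
    return pd.DataFrame(
        scores, index=matrix.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )


def classical_mds_coordinates(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS on pairwise Euclidean row distances.

    Double-centers the squared-distance matrix and embeds on the top
    eigenvectors. For Euclidean input this reproduces PCA scores up to sign.
    Per-axis sign is fixed so the largest-magnitude coordinate is positive.
    """
    X = matrix.to_numpy(dtype=float)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    n = sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:n_components]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    coords, _ = _fix_signs_by(coords, coords)
    return pd.DataFrame(
        coords, index=matrix.index, columns=[f"Dim{i + 1}" for i in range(n_components)]
    )


def ordinate(
    matrix: UsageMatrix | pd.DataFrame,
    method: str = "PCA",
    n_components: int = 2,
) -> pd.DataFrame:
    """Ordinate usage rows by PCA or classical MDS into per-sample coordinates."""
    df = matrix.frequencies if isinstance(matrix, UsageMatrix) else matrix
    if df.shape[0] < 3:
        raise ValueError(f"ordination needs at least 3 samples, got {df.shape[0]}")
    if not (0 < n_components < min(df.shape)):
        raise ValueError(
            f"n_components={n_components} must be in (0, min(n_samples, n_features))"
        )
    method = method.upper()
    if method == "PCA":
        return pca_coordinates(df, n_components)
    if method == "MDS":
        return classical_mds_coordinates(df, n_components)
    raise ValueError(f"unknown ordination method {method!r}")


def sample_diversity_table(
    samples: Iterable[RepertoireSample],
    levels: Sequence[str] = LEVELS,
) -> pd.DataFrame:
    """Tidy per-sample diversity table (the substrate for cohort analysis).

    Columns: patient_id, tissue, chain, isotype, level, richness, shannon,
    nsde, total_count. Empty samples yield missing metric values.
    """
    rows = []
    for s in samples:
        for level in levels:
            prof = collapse(s, level)
            base = {
                "patient_id": s.patient_id,
                "tissue": s.tissue,
                "chain": s.chain,
                "isotype": s.isotype_view or "",
                "level": level,
                "total_count": prof.total,
            }
            if len(prof) == 0:
                rows.append({**base, "richness": np.nan, "shannon": np.nan, "nsde": np.nan})
            else:
                d = diversity(prof)
                rows.append(
                    {**base, "richness": d.richness, "shannon": d.shannon, "nsde": d.nsde}
                )
    return pd.DataFrame(rows)


def paired_similarity_table(
    tumor: Mapping[str, RepertoireSample],
    non_tumor: Mapping[str, RepertoireSample],
    levels: Sequence[str] = LEVELS,
) -> pd.DataFrame:
    """Per-patient tumor vs non-tumor Morisita-Horn similarity.

    ``tumor``/``non_tumor`` map patient id -> sample for one chain/isotype
    view; patients present in both maps are compared at each level.
    """
    rows = []
    for pid in sorted(tumor.keys() & non_tumor.keys()):
        t, n = tumor[pid], non_tumor[pid]
        for level in levels:
            pt, pn = collapse(t, level), collapse(n, level)
            if len(pt) == 0 or len(pn) == 0:
                mhsi, shared = np.nan, 0
            else:
                res = morisita_horn(pt, pn)
                mhsi, shared = res.mhsi, res.n_shared_labels
            rows.append(
                {
                    "patient_id": pid,
                    "chain": t.chain,
                    "isotype": t.isotype_view or "",
                    "level": level,
                    "mhsi": mhsi,
                    "n_shared_labels": shared,
                }
            )
    return pd.DataFrame(rows)
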