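"""Split-half representational dissimilarity matrices and MDS embedding.

The RDM entry for conditions i, j is 1 - r, where r is the Pearson
correlation across ROI voxels between the odd-run mean pattern of i and
the even-run mean pattern of j (runs are 1-indexed: odd = runs 1 and 3,
even = runs 2 and 4). The asymmetric split-half matrix is symmetrized by
averaging r_ij and r_ji; the diagonal (split-half reliability, 1 - r_ii)
is stored but excluded from all inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import smacof

from .cohort import VoxelPatternSet
from .conditions import BODY_PARTS


@dataclass
class DissimilarityMatrix:
    """Symmetric (1 - r) matrix over the ordered body-part conditions."""

    values: np.ndarray
    conditions: tuple[str, ...] = BODY_PARTS
    subject: str | None = None
    group: str | None = None
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.conditions)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match the condition list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.conditions)

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries as a vector (length n(n-1)/2)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.conditions, columns=self.conditions)


@dataclass
class MDSEmbedding:
    """Metric MDS configuration of the conditions with its final stress."""

    coordinates: np.ndarray  # (n_conditions, k)
    stress: float
    conditions: tuple[str, ...] = field(default=BODY_PARTS)


def _half_patterns(patterns: VoxelPatternSet, runs: np.ndarray) -> np.ndarray:
    idx = [patterns.condition_index(c) for c in BODY_PARTS]
    return patterns.betas[runs][:, idx].mean(axis=0)  # (8, n_voxels)


def compute_split_half_rdm(
    patterns: VoxelPatternSet, voxels: np.ndarray | None = None
) -> DissimilarityMatrix:
    """Odd/even split-half correlation RDM for one subject.

    ``voxels`` restricts the pattern to a flat voxel index set (an ROI);
    by default all voxels are used. Raises if any condition-half pattern
    has zero variance across voxels (correlation undefined).
    """
    if patterns.n_runs < 2:
        raise ValueError("split-half RDM needs >= 2 runs")
    runs = np.arange(patterns.n_runs)
    odd = _half_patterns(patterns, runs[::2])   # runs 1, 3, ... (1-indexed)
    even = _half_patterns(patterns, runs[1::2])  # runs 2, 4, ...
    if voxels is not None:
        voxels = np.asarray(voxels)
        if voxels.size < 2:
            raise ValueError("need >= 2 voxels for correlations")
        odd = odd[:, voxels]
        even = even[:, voxels]
    for half, name in ((odd, "odd"), (even, "even")):
        sd = half.std(axis=1)
        if (sd == 0).any():
            bad = BODY_PARTS[int(np.argmax(sd == 0))]
            raise ValueError(f"zero-variance pattern: condition {bad!r}, {name} half")
    zo = (odd - odd.mean(axis=1, keepdims=True)) / odd.std(axis=1, keepdims=True)
    ze = (even - even.mean(axis=1, keepdims=True)) / even.std(axis=1, keepdims=True)
    r = zo @ ze.T / odd.shape[1]  # r[i, j] = corr(odd_i, even_j)
    d = 1.0 - (r + r.T) / 2.0
    return DissimilarityMatrix(
        values=d,
        subject=patterns.subject,
        group=patterns.group,
    )


def aggregate_rdms(
    rdms: list[DissimilarityMatrix], leave_out: str | None = None
) -> DissimilarityMatrix:
    """Element-wise mean RDM, optionally excluding one subject by id."""
    if not rdms:
        raise ValueError("no RDMs to aggregate")
    conditions = rdms[0].conditions
    kept = []
    for m in rdms:
        if m.conditions != conditions:
            raise ValueError("inconsistent condition ordering across RDMs")
        if leave_out is not None and m.subject == leave_out:
            continue
        kept.append(m.values)
    if not kept:
        raise ValueError("all RDMs excluded")
    groups = {m.group for m in rdms if m.group is not None}
    return DissimilarityMatrix(
        values=np.mean(kept, axis=0),
        conditions=conditions,
        group=groups.pop() if len(groups) == 1 else None,
    )


def mds_embed(
    D: DissimilarityMatrix, k: int = 2, seed: int = 0, n_init: int = 8
) -> MDSEmbedding:
    """Metric (stress-minimizing SMACOF) embedding of the RDM in k dimensions."""
    if k <= 0:
        raise ValueError("embedding dimension must be positive")
    if k >= D.n:
        raise ValueError("embedding dimension must be below the condition count")
    coords, stress = smacof(
        D.values,
        n_components=k,
        n_init=n_init,
        random_state=seed,
        normalized_stress=False,
    )
    return MDSEmbedding(coordinates=coords, stress=float(stress), conditions=D.conditions)


# ---------------------------------------------------------------------------
# serialization


def rdm_to_csv(D: DissimilarityMatrix, path: str) -> None:
    D.to_dataframe().to_csv(path)


def rdm_from_csv(path: str) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return DissimilarityMatrix(values=df.to_numpy(), conditions=tuple(df.columns))


def rdm_to_long(D: DissimilarityMatrix) -> pd.DataFrame:
    """Long-format (cond_i, cond_j, dissimilarity) table of the upper triangle."""
    iu = np.triu_indices(D.n, k=1)
    return pd.DataFrame(
        {
            "cond_i": [D.conditions[i] for i in iu[0]],
            "cond_j": [D.conditions[j] for j in iu[1]],
            "dissimilarity": D.values[iu],
        }
    )
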