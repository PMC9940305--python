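"""Distribution comparisons, PCA profiling and fingerprint similarity.

Three views of library diversity:

* pairwise two-sample Kolmogorov-Smirnov tests of every descriptor between
  every unordered pair of groups (the 16 scaffolds plus an optional
  reference set -> C(17, 2) x 7 = 952 comparisons for seven descriptors),
  with a count of highly significant differences (p < 0.001) per
  descriptor;
* principal component analysis of a standardized molecules x descriptors
  matrix (constant columns dropped with a warning);
* a scaffold x scaffold mean-similarity matrix over a pluggable molecular
  fingerprint (default: Morgan/circular, Tanimoto similarity), reporting
  the full-matrix mean and the fraction of cross-scaffold pairs below it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator


@dataclass
class GroupComparison:
    table: pd.DataFrame            # group_a, group_b, descriptor, statistic, pvalue
    n_groups: int
    n_descriptors: int
    significant_counts: dict[str, int]  # per descriptor, p < alpha
    alpha: float

    @property
    def n_comparisons(self) -> int:
        return len(self.table)

    def matrix(self, descriptor: str) -> pd.DataFrame:
        """Symmetric KS-statistic matrix for one descriptor (diagonal 0)."""
        sub = self.table[self.table["descriptor"] == descriptor]
        groups = sorted(set(sub["group_a"]) | set(sub["group_b"]))
        mat = pd.DataFrame(0.0, index=groups, columns=groups)
        for _, row in sub.iterrows():
            mat.loc[row["group_a"], row["group_b"]] = row["statistic"]
            mat.loc[row["group_b"], row["group_a"]] = row["statistic"]
        return mat


def pairwise_ks_matrix(
    groups: Mapping[str, Mapping[str, Sequence[float]]],
    descriptors: Sequence[str],
    alpha: float = 0.001,
) -> GroupComparison:
    """Two-sample KS statistic and asymptotic p-value for every unordered
    group pair and descriptor.

    ``groups`` maps a group label to ``{descriptor: sample}``.  Every group
    must provide a non-empty sample for every descriptor.
    """
    labels = list(groups)
    for label in labels:
        for d in descriptors:
            sample = np.asarray(groups[label][d], dtype=float)
            if sample.size == 0:
                raise ValueError(f"group {label!r} has no values for {d!r}")
    rows = []
    for a, b in itertools.combinations(labels, 2):
        for d in descriptors:
            xa = np.asarray(groups[a][d], dtype=float)
            xb = np.asarray(groups[b][d], dtype=float)
            res = stats.ks_2samp(xa, xb, method="asymp")
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "descriptor": d,
                    "statistic": float(res.statistic),
                    "pvalue": float(res.pvalue),
                }
            )
    table = pd.DataFrame(rows)
    sig = {
        d: int((table[table["descriptor"] == d]["pvalue"] < alpha).sum())
        for d in descriptors
    }
    return GroupComparison(
        table=table,
        n_groups=len(labels),
        n_descriptors=len(descriptors),
        significant_counts=sig,
        alpha=alpha,
    )


@dataclass
class PCAProfile:
    loadings: pd.DataFrame           # features x components
    explained_variance_ratio: np.ndarray
    feature_names: list[str]
    dropped: list[str]


def pca_profile(
    matrix: np.ndarray | pd.DataFrame,
    feature_names: Sequence[str] | None = None,
) -> PCAProfile:
    """PCA of a molecules x descriptors matrix, standardized column-wise.

    Constant columns carry no variance and are dropped with a warning.
    Components are ordered by explained variance; over all components the
    variance fractions sum to 1.
    """
    if isinstance(matrix, pd.DataFrame):
        feature_names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 rows")
    std = X.std(axis=0, ddof=0)
    keep = std > 1e-12
    dropped = [f for f, k in zip(feature_names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant descriptor columns: {dropped}", stacklevel=2)
    X = X[:, keep]
    kept_names = [f for f, k in zip(feature_names, keep) if k]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    pca = PCA()
    pca.fit(Z)
    comp_names = [f"PC{i + 1}" for i in range(pca.components_.shape[0])]
    loadings = pd.DataFrame(pca.components_.T, index=kept_names, columns=comp_names)
    return PCAProfile(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        feature_names=kept_names,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Fingerprint similarity
# ---------------------------------------------------------------------------


def morgan_fingerprint(mol: Chem.Mol):
    """Default pluggable fingerprint: Morgan radius 2, 2048 bits."""
    gen = _morgan_generator()
    return gen.GetFingerprint(mol)


_GEN = None


def _morgan_generator():
    global _GEN
    if _GEN is None:
        _GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    return _GEN


@dataclass
class SimilarityReport:
    matrix: pd.DataFrame       # scaffold x scaffold mean Tanimoto similarity
    matrix_mean: float         # mean over all matrix cells
    below_mean_cross_fraction: float  # cross-scaffold cells below the mean


def similarity_matrix(
    mol_sets: Mapping[str, Sequence[str]],
    fingerprint: Callable[[Chem.Mol], object] | None = None,
) -> SimilarityReport:
    """Mean pairwise fingerprint similarity between (and within) scaffolds.

    ``mol_sets`` maps a scaffold label to SMILES lists.  The diagonal holds
    within-scaffold mean similarity (1.0 for singleton sets); off-diagonal
    cells hold the mean similarity over all cross pairs.  The fingerprint is
    pluggable; the default is a standard circular fingerprint, a documented
    generic substitute for proprietary pharmacophore descriptors.
    """
    if len(mol_sets) < 2:
        raise ValueError("similarity matrix requires at least 2 scaffold sets")
    fp_fn = fingerprint or morgan_fingerprint
    fps: dict[str, list] = {}
    for label, smiles_list in mol_sets.items():
        if not smiles_list:
            raise ValueError(f"scaffold {label!r} has no molecules")
        fps[label] = []
        for smi in smiles_list:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"scaffold {label!r}: bad SMILES {smi!r}")
            fps[label].append(fp_fn(mol))
    labels = list(fps)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i:]:
            if a == b:
                n = len(fps[a])
                if n == 1:
                    mean = 1.0
                else:
                    sims = [
                        DataStructs.TanimotoSimilarity(fps[a][p], fps[a][q])
                        for p in range(n)
                        for q in range(p + 1, n)
                    ]
                    mean = float(np.mean(sims))
            else:
                sims = [
                    DataStructs.TanimotoSimilarity(fa, fb)
                    for fa in fps[a]
                    for fb in fps[b]
                ]
                mean = float(np.mean(sims))
            mat.loc[a, b] = mean
            mat.loc[b, a] = mean
    matrix_mean = float(mat.to_numpy().mean())
    cross = [
        mat.loc[a, b]
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    ]
    below = float(np.mean([c < matrix_mean for c in cross])) if cross else 0.0
    return SimilarityReport(
        matrix=mat, matrix_mean=matrix_mean, below_mean_cross_fraction=below
    )
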