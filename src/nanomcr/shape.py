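"""Molecular shape analysis via normalized principal moments of inertia.

A 3D conformer's three principal moments of inertia I1 <= I2 <= I3 define
the normalized ratios NPR1 = I1/I3 and NPR2 = I2/I3, which place every
rigid body inside the triangle with vertices rod (0, 1), disc (0.5, 0.5)
and sphere (1, 1).  The triangle is partitioned into four sub-triangles by
the edge midpoints (0.25, 0.75), (0.75, 0.75) and (0.5, 1): the three
corner regions keep the vertex labels and the central one is ``hybrid``.
Boundary points are assigned to the corner region (rod, then disc, then
sphere, checked in that order).

One seeded ETKDG conformer per molecule (hydrogens added, MMFF-relaxed when
parameters exist) feeds a mass-weighted inertia tensor; the same tensor
code also accepts explicit coordinates and masses, which is what the
point-mass reference fixtures use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from rdkit import Chem
from rdkit.Chem import AllChem

SHAPE_CLASSES = ("rod", "disc", "sphere", "hybrid")

_ROD = ((0.0, 1.0), (0.25, 0.75), (0.5, 1.0))
_DISC = ((0.5, 0.5), (0.25, 0.75), (0.75, 0.75))
_SPHERE = ((1.0, 1.0), (0.75, 0.75), (0.5, 1.0))
_MAIN = ((0.0, 1.0), (0.5, 0.5), (1.0, 1.0))

_EPS = 1e-9


class EmbeddingError(RuntimeError):
    """3D conformer generation failed for a molecule."""


@dataclass(frozen=True)
class NPRPoint:
    npr1: float
    npr2: float

    @property
    def shape(self) -> str:
        return classify_shape(self.npr1, self.npr2)


def inertia_ratios(coords: np.ndarray, masses: np.ndarray) -> NPRPoint:
    """NPR point from explicit coordinates (n x 3) and masses (n)."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    x = coords - com
    tensor = np.zeros((3, 3))
    r2 = (x**2).sum(axis=1)
    for i in range(3):
        for j in range(3):
            tensor[i, j] = (masses * ((r2 if i == j else 0) - x[:, i] * x[:, j])).sum()
    moments = np.linalg.eigvalsh(tensor)
    i1, i2, i3 = np.clip(moments, 0, None)
    if i3 <= 0:
        raise ValueError("degenerate mass distribution (all mass at one point)")
    return NPRPoint(npr1=float(i1 / i3), npr2=float(i2 / i3))


def npr_from_conformer(
    structure: str,
    seed: int = 42,
    add_hs: bool = True,
    optimize: bool = True,
) -> NPRPoint:
    """Embed one seeded conformer and compute its NPR point.

    Raises :class:`EmbeddingError` when no conformer can be generated; the
    caller logs and excludes such molecules.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"structure does not parse: {structure!r}")
    if add_hs:
        mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise EmbeddingError(f"conformer embedding failed for {structure!r}")
    if optimize:
        try:
            AllChem.MMFFOptimizeMolecule(mol)
        except Exception:
            pass  # keep the raw ETKDG geometry when MMFF lacks parameters
    conf = mol.GetConformer()
    coords = conf.GetPositions()
    masses = np.array([a.GetMass() for a in mol.GetAtoms()])
    return inertia_ratios(coords, masses)


def _in_triangle(p: tuple[float, float], tri) -> bool:
    (x1, y1), (x2, y2), (x3, y3) = tri
    det = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
    a = ((y2 - y3) * (p[0] - x3) + (x3 - x2) * (p[1] - y3)) / det
    b = ((y3 - y1) * (p[0] - x3) + (x1 - x3) * (p[1] - y3)) / det
    c = 1 - a - b
    return min(a, b, c) >= -_EPS


def classify_shape(npr1: float, npr2: float) -> str:
    """Assign an NPR point to rod / disc / sphere / hybrid.

    Points on sub-triangle boundaries go to the corner regions (checked rod,
    disc, sphere in that order), so the edge midpoints belong to the corner
    classes.  Points outside the NPR triangle raise ``ValueError``.
    """
    if not (-_EPS <= npr1 <= npr2 + _EPS <= 1 + 2 * _EPS):
        raise ValueError(f"invalid NPR point ({npr1}, {npr2})")
    p = (npr1, npr2)
    if not _in_triangle(p, _MAIN):
        raise ValueError(f"point {p} lies outside the NPR triangle")
    for tri, label in ((_ROD, "rod"), (_DISC, "disc"), (_SPHERE, "sphere")):
        if _in_triangle(p, tri):
            return label
    return "hybrid"


@dataclass(frozen=True)
class ShapeDistribution:
    percentages: dict[str, float]        # per class, summing to 100
    barycenter: tuple[float, float]      # per-axis KDE-weighted means
    barycenter_mode: tuple[float, float] # per-axis KDE argmax alternative
    n: int


def _kde_center(values: np.ndarray) -> tuple[float, float]:
    """(density-weighted mean, density argmax) of a 1D sample via Gaussian
    KDE with Scott bandwidth; degenerate samples fall back to their mean."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) < 1e-12:
        return float(values.mean()), float(values.mean())
    kde = stats.gaussian_kde(values)  # Scott's rule by default
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    dens = kde(grid)
    wmean = float((grid * dens).sum() / dens.sum())
    mode = float(grid[np.argmax(dens)])
    return wmean, mode


def shape_distribution(points: list[NPRPoint]) -> ShapeDistribution:
    """Class percentages and KDE barycenter of a cloud of NPR points."""
    if len(points) < 2:
        raise ValueError("shape distribution requires at least 2 points")
    counts = {cls: 0 for cls in SHAPE_CLASSES}
    for p in points:
        counts[p.shape] += 1
    n = len(points)
    percentages = {cls: 100.0 * c / n for cls, c in counts.items()}
    npr1 = np.array([p.npr1 for p in points])
    npr2 = np.array([p.npr2 for p in points])
    m1, mode1 = _kde_center(npr1)
    m2, mode2 = _kde_center(npr2)
    return ShapeDistribution(
        percentages=percentages,
        barycenter=(m1, m2),
        barycenter_mode=(mode1, mode2),
        n=n,
    )
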