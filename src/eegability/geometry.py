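"""Latent representational geometries planted in synthetic EEG cohorts.

A :class:`LatentGeometry` couples a target representational dissimilarity
matrix (RDM) over the stimulus set with a Gaussian temporal activation
profile and an ability-coupling slope. The default configuration plants a
"midlevel visual" geometry (face/nonface block structure with graded
within-block dissimilarities) peaking near 150 ms and a "semantic" geometry
(category-cluster structure) peaking near 650 ms, both with positive
coupling to face-recognition ability — the generative ground truth that
downstream group contrasts are expected to recover.

Geometries are constructed from explicit low-dimensional point
configurations, so every target RDM is Euclidean-realizable by design;
:func:`classical_mds` recovers the configuration (up to rotation) when the
forward model needs per-stimulus score vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from ._rng import rng_for
from .stimuli import StimulusSet

__all__ = [
    "GeometrySpec",
    "LatentGeometry",
    "make_latent_geometries",
    "default_geometry_specs",
    "classical_mds",
]


@dataclass(frozen=True)
class GeometrySpec:
    """Configuration for one planted geometry.

    kind:
        'block'    — face/nonface block offset plus graded within-block
                     structure (midlevel-visual-like);
        'category' — one cluster per stimulus category with random
                     between-cluster distances (semantic-like);
        'random'   — unstructured Gaussian point cloud (control).
    center_ms / width_ms:
        center and standard deviation (ms) of the Gaussian time profile.
    ability_coupling:
        slope of the per-participant gain in units of gain per ability SD.
    amplitude:
        peak signal scale (per-channel SD at profile peak for an
        average-ability participant).
    categories:
        optional restriction of the geometry's support to a subset of
        stimulus categories; unsupported stimuli evoke nothing.
    """

    name: str
    kind: str = "block"
    center_ms: float = 150.0
    width_ms: float = 30.0
    ability_coupling: float = 0.0
    amplitude: float = 1.0
    n_dims: int = 4
    categories: tuple[str, ...] | None = None


@dataclass(frozen=True)
class LatentGeometry:
    """A realized planted geometry over a fixed stimulus set."""

    name: str
    target_rdm: np.ndarray = field(repr=False)
    center_ms: float = 150.0
    width_ms: float = 30.0
    ability_coupling: float = 0.0
    amplitude: float = 1.0
    support: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.target_rdm, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("target_rdm must be square")
        if not np.allclose(d, d.T):
            raise ValueError("target_rdm must be symmetric")
        if np.any(d < 0):
            raise ValueError("target_rdm must be nonnegative")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("target_rdm must have a zero diagonal")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")

    @property
    def n_stimuli(self) -> int:
        return self.target_rdm.shape[0]

    def profile(self, times_ms: np.ndarray) -> np.ndarray:
        """Nonnegative Gaussian activation gain per time sample (peak 1)."""
        t = np.asarray(times_ms, dtype=float)
        return np.exp(-0.5 * ((t - self.center_ms) / self.width_ms) ** 2)

    def window_ms(self) -> tuple[float, float]:
        """The planted window: center ± one profile SD."""
        return (self.center_ms - self.width_ms, self.center_ms + self.width_ms)


def classical_mds(
    rdm: np.ndarray, n_components: int = 10
) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) multidimensional scaling of a dissimilarity matrix.

    Returns ``(coords, stress)`` where ``coords`` is (n_stimuli, d) with
    d ≤ n_components, and ``stress`` is the relative residual: the fraction
    of positive double-centered eigenvalue mass not captured by the
    retained dimensions (0 for an exactly Euclidean-realizable input).
    """
    d = np.asarray(rdm, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-9 * abs(evals[0]))
    keep = np.flatnonzero(pos)[:n_components]
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    total = evals[pos].sum()
    stress = 0.0 if total == 0 else float(1.0 - evals[keep].sum() / total)
    return coords, stress


def _block_points(stimuli: StimulusSet, n_dims: int, rng: np.random.Generator) -> np.ndarray:
    """Graded within-block structure + a face/nonface offset dimension.

    The offset is placed in a dedicated dimension and scaled to 1.2× the
    largest within-block distance, guaranteeing every cross-block pair is
    farther apart than any within-block pair.
    """
    n = stimuli.n_stimuli
    pts = rng.normal(size=(n, n_dims))
    offset_col = np.zeros((n, 1))
    is_face = stimuli.is_face
    if is_face.any() and (~is_face).any():
        within = max(
            pdist(pts[is_face]).max(initial=0.0),
            pdist(pts[~is_face]).max(initial=0.0),
        )
        offset_col[~is_face] = 1.2 * within if within > 0 else 1.0
    return np.hstack([pts, offset_col])


def _category_points(stimuli: StimulusSet, n_dims: int, rng: np.random.Generator) -> np.ndarray:
    cats = stimuli.categories()
    levels = list(dict.fromkeys(cats))
    centroids = {c: rng.normal(scale=2.0, size=n_dims) for c in levels}
    pts = np.stack([centroids[c] for c in cats])
    pts += rng.normal(scale=0.6, size=pts.shape)
    return pts


def _realize(spec: GeometrySpec, stimuli: StimulusSet, rng: np.random.Generator) -> LatentGeometry:
    if spec.kind == "block":
        pts = _block_points(stimuli, spec.n_dims, rng)
    elif spec.kind == "category":
        pts = _category_points(stimuli, spec.n_dims, rng)
    elif spec.kind == "random":
        pts = rng.normal(size=(stimuli.n_stimuli, spec.n_dims))
    else:
        raise ValueError(f"unknown geometry kind: {spec.kind!r}")

    support = None
    if spec.categories is not None:
        support = np.isin(stimuli.categories(), list(spec.categories))
        pts = pts.copy()
        pts[~support] = 0.0

    rdm = squareform(pdist(pts))
    return LatentGeometry(
        name=spec.name,
        target_rdm=rdm,
        center_ms=spec.center_ms,
        width_ms=spec.width_ms,
        ability_coupling=spec.ability_coupling,
        amplitude=spec.amplitude,
        support=support,
    )


def default_geometry_specs() -> list[GeometrySpec]:
    """Midlevel-visual geometry near 150 ms and semantic geometry near 650 ms,
    both positively coupled to ability."""
    return [
        GeometrySpec(
            name="midlevel_visual",
            kind="block",
            center_ms=150.0,
            width_ms=20.0,
            ability_coupling=0.5,
        ),
        GeometrySpec(
            name="semantic",
            kind="category",
            center_ms=650.0,
            width_ms=50.0,
            ability_coupling=0.5,
        ),
    ]


def make_latent_geometries(
    stimuli: StimulusSet,
    specs: list[GeometrySpec] | None = None,
    *,
    seed: int = 0,
    max_pairwise_spearman: float = 0.7,
) -> list[LatentGeometry]:
    """Realize a list of geometry specs over ``stimuli``.

    Distinct geometries must be distinguishable downstream, so the pairwise
    Spearman correlation between the vectorized target RDMs is checked
    against ``max_pairwise_spearman`` and a violation raises.
    """
    if specs is None:
        specs = default_geometry_specs()
    if not specs:
        raise ValueError("at least one geometry spec required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("geometry names must be unique")

    rng = rng_for(seed, "geometries")
    geoms = [_realize(s, stimuli, rng) for s in specs]

    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            vi = squareform(geoms[i].target_rdm, checks=False)
            vj = squareform(geoms[j].target_rdm, checks=False)
            rho = spearmanr(vi, vj).statistic
            if np.isfinite(rho) and abs(rho) > max_pairwise_spearman:
                raise ValueError(
                    f"geometries {names[i]!r} and {names[j]!r} are too "
                    f"correlated (|rho|={abs(rho):.2f} > {max_pairwise_spearman})"
                )
    return geoms
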