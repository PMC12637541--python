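"""Ground-truthed synthetic fixtures for the full pipeline.

Three generators emulate the three kinds of input the toolkit consumes:

* :func:`simulate_image_stack` — multi-bit fluorescence stacks with
  molecules planted per a codebook, Gaussian-PSF blur, illumination
  vignetting, per-bit integer drift, additive Gaussian (optionally
  Poisson) noise, and a DAPI-like anchor channel per round for drift
  estimation.  Blanks are never planted, so any decoded blank is a false
  discovery by construction.
* :func:`simulate_cell_map` — 3D cell maps with layered anatomy, planted
  expression gradients, and tubular vessel-cell arrangements along
  polyline centerlines, sectioned at constant spacing.
* :func:`simulate_layer_meshes` — nested closed surfaces (spheres or
  ellipsoids) with known analytic thickness.

Every generator is bit-reproducible under a fixed seed and returns the
ground truth needed to score downstream recall/precision.

Coordinates are 0-based pixels in ``(z, y, x)`` order for image stacks
and micrometres in ``(x, y, z)`` columns for cell maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .codebook import Codebook, generate_codebook
from .stack import ImageStack

__all__ = [
    "PlantedMoleculeSet",
    "plant_random_molecules",
    "simulate_image_stack",
    "standard_decoding_fixture",
    "CellMapConfig",
    "VesselSpec",
    "GradientSpec",
    "simulate_cell_map",
    "simulate_layer_meshes",
    "gaussian_psf",
]


def gaussian_psf(sigma: float = 1.2, radius: int = 4) -> np.ndarray:
    """Unit-sum isotropic 2D Gaussian PSF on a (2r+1)^2 grid."""
    ax = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(ax**2) / (2 * sigma**2))
    psf = np.outer(g, g)
    return psf / psf.sum()


@dataclass
class PlantedMoleculeSet:
    """Molecules to plant plus per-stack imaging imperfections.

    ``positions`` are float pixel coordinates ``(z, y, x)``; ``drift`` is
    one integer ``(dz, dy, dx)`` offset per bit applied to every molecule
    in that bit's image; ``dropout_bits`` optionally zeroes one on-bit per
    listed molecule to exercise single-bit error correction.
    """

    genes: list[str]
    positions: np.ndarray
    amplitudes: np.ndarray
    shape: tuple[int, int, int]
    psf_sigma: float = 1.2
    drift: np.ndarray | None = None
    illumination: np.ndarray | None = None
    noise_sigma: float = 0.0
    poisson_noise: bool = False
    dropout_bits: dict[int, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")
        lo_ok = (self.positions >= 0).all()
        hi_ok = (self.positions < np.asarray(self.shape)).all()
        if not (lo_ok and hi_ok):
            raise ValueError("molecule position outside stack bounds")


def plant_random_molecules(
    codebook: Codebook,
    n_molecules: int,
    shape: tuple[int, int, int],
    seed: int = 0,
    *,
    amplitude: float = 8000.0,
    amplitude_cv: float = 0.0,
    min_separation: float = 12.0,
    margin: int = 6,
    **imaging_kwargs,
) -> PlantedMoleculeSet:
    """Scatter molecules of random (non-blank) genes with a minimum spacing.

    Positions are dart-thrown until pairwise in-plane separation exceeds
    ``min_separation`` so planted molecules decode as distinct connected
    components; the separation is enforced across z-planes too because
    normalization is scale-invariant and even faint PSF tails decode to
    their gene.  Blank entries are never drawn.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    genes = [n for n, b in zip(codebook.names, codebook.is_blank) if not b]
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < n_molecules:
        attempts += 1
        if attempts > 200 * n_molecules:
            raise ValueError("could not place molecules at the requested separation")
        z = rng.integers(0, nz)
        y = rng.uniform(margin, ny - margin - 1)
        x = rng.uniform(margin, nx - margin - 1)
        cand = np.array([z, y, x], dtype=float)
        if positions:
            arr = np.array(positions)
            # Chebyshev metric matches the square PSF render footprint
            d = np.maximum(np.abs(arr[:, 1] - y), np.abs(arr[:, 2] - x))
            if d.min() < min_separation:
                continue
        positions.append(cand)
    chosen = rng.choice(len(genes), size=n_molecules)
    amps = amplitude * np.ones(n_molecules)
    if amplitude_cv > 0:
        amps *= rng.lognormal(mean=0.0, sigma=amplitude_cv, size=n_molecules)
    return PlantedMoleculeSet(
        genes=[genes[i] for i in chosen],
        positions=np.array(positions),
        amplitudes=amps,
        shape=shape,
        seed=seed,
        **imaging_kwargs,
    )


def _render_spot(plane: np.ndarray, y: float, x: float, amp: float, sigma: float) -> None:
    """Add a 2D Gaussian of peak ``amp`` at (y, x) in place."""
    ny, nx = plane.shape
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(y) - r), min(ny, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(nx, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    plane[y0:y1, x0:x1] += amp * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
    )


def simulate_image_stack(
    codebook: Codebook,
    planted: PlantedMoleculeSet,
    *,
    n_anchors: int = 40,
    anchor_amplitude: float = 5000.0,
    n_colors: int = 2,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a bits x z x y x x stack from planted molecules.

    Each molecule contributes a PSF-shaped spot at its position, shifted
    by the per-bit drift, in exactly the on-bits of its gene's barcode
    (minus any planted dropout), then the frame is multiplied by the
    illumination field and Gaussian/Poisson noise is added.  A shared
    random anchor point cloud is rendered once per imaging round (shifted
    by that round's drift) as a DAPI-like channel.

    Returns the stack and the ground-truth molecule table
    (gene, z, y, x, amplitude).
    """
    n_bits = codebook.n_bits
    nz, ny, nx = planted.shape
    drift = planted.drift
    if drift is None:
        drift = np.zeros((n_bits, 3), dtype=int)
    drift = np.asarray(drift, dtype=int)
    if drift.shape != (n_bits, 3):
        raise ValueError(f"drift must be ({n_bits}, 3)")
    if (np.abs(drift) >= np.asarray(planted.shape)).any():
        raise ValueError("drift offsets exceed stack extent")

    rng = np.random.default_rng(planted.seed)
    data = np.zeros((n_bits, nz, ny, nx), dtype=float)
    name_to_idx = {n: i for i, n in enumerate(codebook.names)}
    for m, (gene, pos, amp) in enumerate(
        zip(planted.genes, planted.positions, planted.amplitudes)
    ):
        barcode = codebook.barcodes[name_to_idx[gene]]
        on_bits = np.flatnonzero(barcode)
        drop = planted.dropout_bits.get(m)
        for bit in on_bits:
            if drop is not None and bit == drop:
                continue
            dz, dy, dx = drift[bit]
            z = int(round(pos[0])) + dz
            if not 0 <= z < nz:
                continue
            _render_spot(data[bit, z], pos[1] + dy, pos[2] + dx, amp, planted.psf_sigma)

    if planted.illumination is not None:
        illum = np.asarray(planted.illumination, dtype=float)
        if illum.shape != (ny, nx):
            raise ValueError("illumination field must match (y, x) shape")
        data *= illum[None, None]
    if planted.poisson_noise:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    if planted.noise_sigma > 0:
        data += rng.normal(0.0, planted.noise_sigma, size=data.shape)
        np.clip(data, 0, None, out=data)

    # shared anchor point cloud, one DAPI-like volume per imaging round
    n_rounds = int(np.ceil(n_bits / n_colors))
    anchor_pts = np.column_stack(
        [
            rng.integers(0, nz, n_anchors),
            rng.uniform(4, ny - 5, n_anchors),
            rng.uniform(4, nx - 5, n_anchors),
        ]
    )
    anchors = np.zeros((n_rounds, nz, ny, nx), dtype=float)
    for rnd in range(n_rounds):
        dz, dy, dx = drift[min(rnd * n_colors, n_bits - 1)]
        for z, y, x in anchor_pts:
            zz = int(round(z)) + dz
            if 0 <= zz < nz:
                _render_spot(anchors[rnd, zz], y + dy, x + dx, anchor_amplitude, 1.5)

    stack = ImageStack(
        data=data,
        n_colors=n_colors,
        drift=drift,
        anchors=anchors,
    )
    truth = pd.DataFrame(
        {
            "gene": planted.genes,
            "z": planted.positions[:, 0],
            "y": planted.positions[:, 1],
            "x": planted.positions[:, 2],
            "amplitude": planted.amplitudes,
        }
    )
    return stack, truth


def standard_decoding_fixture(
    seed: int = 11,
    *,
    noisy: bool = True,
    n_genes: int = 100,
    n_blanks: int = 40,
    n_bits: int = 16,
    n_molecules: int = 500,
    shape: tuple[int, int, int] = (3, 400, 400),
) -> tuple[Codebook, "ImageStack", pd.DataFrame]:
    """The standard decoding study conditions used throughout the suite.

    A 16-bit codebook of 100 genes plus 40 blanks with 500 planted
    molecules on a 3 x 400 x 400 stack; the noisy variant adds lognormal
    amplitude scatter (CV 0.5 around peak 8000) and additive Gaussian
    background (sigma 300, about 4% of peak).  Returns
    ``(codebook, raw stack, ground truth)``; run the preprocessing chain
    before decoding.
    """
    codebook = generate_codebook(n_bits, n_genes, n_blanks, seed=42)
    planted = plant_random_molecules(
        codebook,
        n_molecules,
        shape,
        seed=seed,
        amplitude=8000.0,
        amplitude_cv=0.5 if noisy else 0.0,
        noise_sigma=300.0 if noisy else 0.0,
    )
    stack, truth = simulate_image_stack(codebook, planted)
    return codebook, stack, truth


@dataclass
class VesselSpec:
    """A tubular cell arrangement along a 3D polyline centerline (μm)."""

    centerline: np.ndarray
    radius: float = 20.0
    cells_per_section: int = 12
    cell_type: str = "VSMC"
    marker_gene: str = "MYH11"
    marker_level: float = 50.0


@dataclass
class GradientSpec:
    """Linear expression gradient for one gene along one spatial axis."""

    gene: str
    axis: int = 0  # 0=x, 1=y, 2=z
    slope: float = 1.0
    base: float = 5.0
    cell_type: str | None = None


@dataclass
class CellMapConfig:
    """Study conditions for the synthetic 3D cell map.

    ``extent`` is the (x, y, z) box in μm; ``section_spacing`` the
    constant z distance between tissue sections; ``background_types``
    maps cell-type label -> count of uniformly scattered cells.
    """

    extent: tuple[float, float, float] = (1000.0, 1000.0, 600.0)
    section_spacing: float = 30.0
    background_types: dict[str, int] = field(
        default_factory=lambda: {"vCM": 3000, "Fibro": 1500, "BEC": 800}
    )
    genes: tuple[str, ...] = ("MYH11", "NPPA", "HEY2")
    base_expression: float = 5.0
    vessels: list[VesselSpec] = field(default_factory=list)
    gradients: list[GradientSpec] = field(default_factory=list)
    noise_dispersion: float = 1.0
    seed: int = 0


def simulate_cell_map(config: CellMapConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a sectioned 3D cell map with planted structure.

    Returns a cell table with columns ``cell_id, x, y, z, section,
    cell_type`` plus one count column per gene, and a ground-truth dict
    (vessel memberships per vessel, gradient specs).  Expression counts
    are Poisson draws around the planted means.
    """
    rng = np.random.default_rng(config.seed)
    ex, ey, ez = config.extent
    n_sections = int(np.floor(ez / config.section_spacing)) + 1
    rows: list[dict] = []
    truth: dict = {"vessel_cells": [], "gradients": list(config.gradients)}

    def section_of(z: float) -> int:
        return int(round(z / config.section_spacing))

    for ctype, count in config.background_types.items():
        xs = rng.uniform(0, ex, count)
        ys = rng.uniform(0, ey, count)
        secs = rng.integers(0, n_sections, count)
        for x, y, s in zip(xs, ys, secs):
            rows.append(
                {"x": x, "y": y, "z": s * config.section_spacing, "section": int(s),
                 "cell_type": ctype}
            )

    for v in config.vessels:
        cl = np.asarray(v.centerline, dtype=float)
        if (cl < 0).any() or (cl > np.array(config.extent)).any():
            raise ValueError("vessel centerline outside the tissue volume")
        members: list[int] = []
        # sample the centerline where it crosses each section plane
        for s in range(n_sections):
            zs = s * config.section_spacing
            pt = _polyline_point_at_z(cl, zs)
            if pt is None:
                continue
            for _ in range(v.cells_per_section):
                ang = rng.uniform(0, 2 * np.pi)
                r = v.radius * np.sqrt(rng.uniform())
                x = float(np.clip(pt[0] + r * np.cos(ang), 0, ex))
                y = float(np.clip(pt[1] + r * np.sin(ang), 0, ey))
                members.append(len(rows))
                rows.append(
                    {"x": x, "y": y, "z": zs, "section": s, "cell_type": v.cell_type,
                     "_marker": (v.marker_gene, v.marker_level)}
                )
        truth["vessel_cells"].append(members)

    cells = pd.DataFrame(rows)
    cells.insert(0, "cell_id", np.arange(len(cells)))
    for gene in config.genes:
        mean = np.full(len(cells), config.base_expression, dtype=float)
        if "_marker" in cells.columns:
            for i, mk in enumerate(cells["_marker"]):
                if isinstance(mk, tuple) and mk[0] == gene:
                    mean[i] = mk[1]
        for g in config.gradients:
            if g.gene != gene:
                continue
            coord = cells[["x", "y", "z"]].to_numpy()[:, g.axis]
            frac = coord / config.extent[g.axis]
            contrib = g.base + g.slope * frac * config.extent[g.axis]
            sel = np.ones(len(cells), bool) if g.cell_type is None else (
                cells["cell_type"] == g.cell_type
            ).to_numpy()
            mean[sel] = np.clip(contrib[sel], 0.05, None)
        counts = rng.poisson(mean * config.noise_dispersion)
        cells[gene] = counts
    if "_marker" in cells.columns:
        cells = cells.drop(columns="_marker")
    return cells, truth


def _polyline_point_at_z(polyline: np.ndarray, z: float) -> np.ndarray | None:
    """First (x, y, z) point where the polyline crosses height ``z``."""
    for a, b in zip(polyline[:-1], polyline[1:]):
        z0, z1 = a[2], b[2]
        if min(z0, z1) - 1e-9 <= z <= max(z0, z1) + 1e-9:
            if abs(z1 - z0) < 1e-12:
                return a.copy()
            t = (z - z0) / (z1 - z0)
            return a + t * (b - a)
    return None


def simulate_layer_meshes(
    radii: list[float],
    subdivisions: int = 3,
    *,
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[trimesh.Trimesh]:
    """Concentric sphere (or ellipsoid) meshes ordered outer to inner.

    Analytic layer thickness between consecutive concentric spheres i and
    i+1 is ``r_i - r_{i+1}`` at every vertex.  ``scale`` turns the spheres
    into ellipsoids with axes ``radius * scale``.
    """
    radii = list(radii)
    if any(b >= a for a, b in zip(radii[:-1], radii[1:])):
        raise ValueError("radii must be strictly decreasing (outer to inner)")
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    meshes = []
    for r in radii:
        m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=r)
        if scale != (1.0, 1.0, 1.0):
            m.apply_scale(scale)
        meshes.append(m)
    return meshes
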