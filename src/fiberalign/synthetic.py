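"""Synthetic phalloidin-style micrographs with known fiber orientations.

Endothelial monolayers exposed to laminar shear stress (LSS) remodel their
actin cytoskeleton so that stress fibers point along the flow axis.  No
imaging dataset accompanies the analysis this package implements, so this
module generates stand-in micrographs: fields of elliptical cells filled
with bright linear fibers whose orientations follow an axial (180-degree
periodic) von Mises law around the flow axis.  The concentration parameter
``kappa`` is the single alignment knob -- zero for unaligned (static or
sparse) conditions, rising with flow duration for confluent monolayers.

Angle convention (binding for the whole package): orientations are in
degrees, axial (mod 180), measured counterclockwise from the flow axis,
with the flow axis along the increasing image-column direction in a
mathematical y-up frame.  Image arrays are row-major with the row index
increasing downward, so any gradient-based angle computation negates the
row component.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ConditionLabel",
    "SyntheticSpec",
    "GroundTruth",
    "PlacementError",
    "sample_axial_orientations",
    "render_image",
    "generate_experiment",
    "default_kappa_profile",
    "default_design",
    "simulate_replicate_table",
]


class PlacementError(RuntimeError):
    """Raised when disjoint cell placement fails within the retry budget."""


@dataclass(frozen=True)
class ConditionLabel:
    """Experimental condition metadata for one image.

    ``shear_dyn_cm2`` is carried as a label only; the mechanics of flow are
    never modeled.
    """

    cell_type: str = "HUVEC"
    density: str = "confluent"  # confluent | sparse
    exposure: str = "static"  # static | LSS
    duration_h: float = 0.0
    shear_dyn_cm2: float = 15.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.density not in ("confluent", "sparse"):
            raise ValueError(f"density must be confluent|sparse, got {self.density!r}")
        if self.exposure not in ("static", "LSS"):
            raise ValueError(f"exposure must be static|LSS, got {self.exposure!r}")
        if self.exposure == "static" and self.duration_h != 0:
            raise ValueError("static exposure requires duration_h = 0")
        if self.duration_h < 0:
            raise ValueError("duration_h must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")

    @property
    def level(self) -> str:
        """Flow-condition level string used by the factorial analysis."""
        if self.exposure == "static":
            return "static"
        return f"LSS_{self.duration_h:g}h"

    def key(self) -> tuple:
        return (self.cell_type, self.density, self.exposure, self.duration_h, self.replicate)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one simulated micrograph.

    Defaults describe a 256x256 field of 36 cells with 12 fibers each, so a
    three-replicate condition holds 108 simulated cells (matching a design
    of >100 cells per condition).  Sparse layouts place disjoint cells
    covering ~10% of the field, mirroring seeding at 10% of confluent
    density.
    """

    width: int = 256
    height: int = 256
    layout: str = "confluent"  # confluent | sparse
    coverage_fraction: float = 1.0  # 1.0 confluent, <=0.10 sparse
    n_cells: int = 36
    fibers_per_cell: int = 12
    mu: float = 0.0  # axial mean orientation, degrees; flow axis = 0
    kappa: float = 0.0  # axial von Mises concentration, >= 0
    fiber_length_px: tuple[float, float] = (28.0, 7.0)  # mean, sd
    fiber_width_px: float = 1.5  # Gaussian cross-section sigma
    fiber_intensity: float = 1800.0
    background_level: float = 200.0
    noise_sd: float = 40.0
    seed: int = 0
    condition: ConditionLabel = field(default_factory=ConditionLabel)

    def __post_init__(self) -> None:
        if self.layout not in ("confluent", "sparse"):
            raise ValueError(f"layout must be confluent|sparse, got {self.layout!r}")
        if self.layout == "sparse" and self.coverage_fraction > 0.10 + 1e-12:
            raise ValueError("sparse layout requires coverage_fraction <= 0.10")
        if self.layout == "confluent" and self.coverage_fraction != 1.0:
            raise ValueError("confluent layout requires coverage_fraction = 1.0")
        if not (0 < self.coverage_fraction <= 1.0):
            raise ValueError("coverage_fraction must lie in (0, 1]")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.fibers_per_cell < 0:
            raise ValueError("fibers_per_cell must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not (0 <= self.mu < 180):
            raise ValueError("mu must lie in [0, 180)")
        if self.fiber_width_px <= 0:
            raise ValueError("fiber_width_px must be positive")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("background_level and noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Per-fiber ground truth recorded alongside each rendered image."""

    true_orientations: list[float]
    fiber_endpoints: list[tuple[tuple[float, float], tuple[float, float]]]
    cell_centroids: list[tuple[float, float]]
    mu: float
    kappa: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_orientations": self.true_orientations,
                "fiber_endpoints": self.fiber_endpoints,
                "cell_centroids": self.cell_centroids,
                "mu": self.mu,
                "kappa": self.kappa,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            true_orientations=list(d["true_orientations"]),
            fiber_endpoints=[((a[0][0], a[0][1]), (a[1][0], a[1][1])) for a in d["fiber_endpoints"]],
            cell_centroids=[(c[0], c[1]) for c in d["cell_centroids"]],
            mu=d["mu"],
            kappa=d["kappa"],
        )


def sample_axial_orientations(
    n: int,
    mu: float,
    kappa: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` axial orientations (degrees in [0, 180)).

    Axial sampling uses the angle-doubling construction: draw phi from a
    von Mises distribution with location ``2*mu`` and concentration
    ``kappa`` on the full circle, then return ``theta = (phi/2) mod 180``.
    ``kappa = 0`` yields the uniform axial law.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if not (0 <= mu < 180):
        raise ValueError("mu must lie in [0, 180)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    phi = rng.vonmises(np.deg2rad(2.0 * mu), kappa, size=n)
    return (np.rad2deg(phi) / 2.0) % 180.0


def _cell_layout(spec: SyntheticSpec, rng: np.random.Generator):
    """Place cells as ellipses; returns list of (cy, cx, a, b, angle_deg).

    Confluent: jittered tiling that covers the whole field.  Sparse:
    disjoint ellipses (bounding-circle test) covering ~coverage_fraction of
    the field, with a bounded rejection-sampling budget.
    """
    H, W = spec.height, spec.width
    cells = []
    if spec.layout == "confluent":
        ncols = int(np.ceil(np.sqrt(spec.n_cells * W / H)))
        nrows = int(np.ceil(spec.n_cells / ncols))
        tile_w, tile_h = W / ncols, H / nrows
        k = 0
        for i in range(nrows):
            for j in range(ncols):
                if k >= spec.n_cells:
                    break
                cy = (i + 0.5) * tile_h + rng.uniform(-0.1, 0.1) * tile_h
                cx = (j + 0.5) * tile_w + rng.uniform(-0.1, 0.1) * tile_w
                # semi-axes slightly above half-tile so neighbours overlap
                a = 0.70 * max(tile_h, tile_w)
                b = 0.70 * min(tile_h, tile_w)
                ang = rng.uniform(0, 180)
                cells.append((cy, cx, a, b, ang))
                k += 1
        return cells
    # sparse: elongated disjoint ellipses at the requested coverage
    area_per_cell = spec.coverage_fraction * W * H / spec.n_cells
    aspect = 1.8
    a = np.sqrt(area_per_cell * aspect / np.pi)
    b = np.sqrt(area_per_cell / (aspect * np.pi))
    r_bound = a  # bounding-circle radius
    margin = 2.0
    for _ in range(spec.n_cells):
        placed = False
        for _attempt in range(1000):
            cy = rng.uniform(r_bound, H - r_bound)
            cx = rng.uniform(r_bound, W - r_bound)
            if all(np.hypot(cy - y0, cx - x0) > 2 * r_bound + margin for y0, x0, *_ in cells):
                cells.append((cy, cx, a, b, rng.uniform(0, 180)))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {spec.n_cells} disjoint cells of radius {r_bound:.1f} px "
                f"in a {W}x{H} field at coverage {spec.coverage_fraction}: "
                "reduce n_cells or coverage_fraction"
            )
    return cells


def _clip_segment_to_ellipse(cy, cx, a, b, ang_deg, py, px, theta_deg, half_len):
    """Intersect the fiber segment with its cell ellipse; return t-range.

    The segment is ``(py, px) + t * u`` for ``t`` in [-half_len, half_len],
    with u the unit direction of ``theta_deg`` in array coordinates.  Points
    inside the ellipse satisfy a quadratic in t <= 1.
    """
    th = np.deg2rad(theta_deg)
    # array coords: col increases with cos(theta), row decreases with sin(theta)
    ur, uc = -np.sin(th), np.cos(th)
    ca, sa = np.cos(np.deg2rad(ang_deg)), np.sin(np.deg2rad(ang_deg))
    # transform into the ellipse frame (x along semi-axis a)

    def to_ellipse(r, c):
        dx, dy = c - cx, -(r - cy)  # y-up
        return (dx * ca + dy * sa), (-dx * sa + dy * ca)

    x0, y0 = to_ellipse(py, px)
    x1, y1 = to_ellipse(py + ur, px + uc)
    vx, vy = x1 - x0, y1 - y0
    A = (vx / a) ** 2 + (vy / b) ** 2
    B = 2 * (x0 * vx / a**2 + y0 * vy / b**2)
    C = (x0 / a) ** 2 + (y0 / b) ** 2 - 1.0
    if A < 1e-12:
        return (-half_len, half_len) if C <= 0 else None
    disc = B * B - 4 * A * C
    if disc <= 0:
        return None
    sq = np.sqrt(disc)
    t_lo, t_hi = (-B - sq) / (2 * A), (-B + sq) / (2 * A)
    t_lo, t_hi = max(t_lo, -half_len), min(t_hi, half_len)
    if t_lo >= t_hi:
        return None
    return t_lo, t_hi


def _render_fiber(img, p0, p1, sigma, amplitude):
    """Additively render one segment with a Gaussian cross-section."""
    H, W = img.shape
    pad = int(np.ceil(4 * sigma)) + 1
    r_lo = max(int(np.floor(min(p0[0], p1[0]))) - pad, 0)
    r_hi = min(int(np.ceil(max(p0[0], p1[0]))) + pad + 1, H)
    c_lo = max(int(np.floor(min(p0[1], p1[1]))) - pad, 0)
    c_hi = min(int(np.ceil(max(p0[1], p1[1]))) + pad + 1, W)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    wr, wc = p1[0] - p0[0], p1[1] - p0[1]
    vv = wr * wr + wc * wc
    vr, vc = rr - p0[0], cc - p0[1]
    t = np.clip((vr * wr + vc * wc) / vv, 0.0, 1.0) if vv > 0 else 0.0
    d2 = (vr - t * wr) ** 2 + (vc - t * wc) ** 2
    img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(-d2 / (2 * sigma**2))


def render_image(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one micrograph; returns (float image, ground truth).

    Cells are ellipses (jitter-tiled for confluent, disjoint for sparse);
    each contains ``fibers_per_cell`` straight segments with axial von Mises
    orientations, a Gaussian cross-section of sigma ``fiber_width_px``, and
    lengths clipped to the cell boundary and image bounds.  Additive
    Gaussian noise of sd ``noise_sd`` sits on ``background_level``.  Output
    is deterministic in (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    img = np.zeros((H, W), dtype=np.float64)

    cells = _cell_layout(spec, rng)
    orientations: list[float] = []
    endpoints: list[tuple[tuple[float, float], tuple[float, float]]] = []
    mean_len, sd_len = spec.fiber_length_px

    for cy, cx, a, b, ang in cells:
        if spec.fibers_per_cell == 0:
            continue
        thetas = sample_axial_orientations(spec.fibers_per_cell, spec.mu, spec.kappa, rng)
        for theta in thetas:
            # fiber anchor inside the ellipse (rejection on the unit disk)
            while True:
                ex = rng.uniform(-1, 1)
                ey = rng.uniform(-1, 1)
                if ex * ex + ey * ey <= 1:
                    break
            ca, sa = np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))
            dx = 0.8 * (ex * a * ca - ey * b * sa)
            dy = 0.8 * (ex * a * sa + ey * b * ca)
            px, py = cx + dx, cy - dy  # y-up back to row coords
            half_len = max(rng.normal(mean_len, sd_len), 4.0) / 2.0
            t_range = _clip_segment_to_ellipse(cy, cx, a, b, ang, py, px, theta, half_len)
            if t_range is None:
                t_range = (-half_len, half_len)
            th = np.deg2rad(theta)
            ur, uc = -np.sin(th), np.cos(th)
            p0 = (py + t_range[0] * ur, px + t_range[0] * uc)
            p1 = (py + t_range[1] * ur, px + t_range[1] * uc)
            # keep endpoints inside image bounds
            p0 = (float(np.clip(p0[0], 0, H - 1)), float(np.clip(p0[1], 0, W - 1)))
            p1 = (float(np.clip(p1[0], 0, H - 1)), float(np.clip(p1[1], 0, W - 1)))
            _render_fiber(img, p0, p1, spec.fiber_width_px, spec.fiber_intensity)
            orientations.append(float(theta))
            endpoints.append((p0, p1))

    img += spec.background_level
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, None, out=img)

    gt = GroundTruth(
        true_orientations=orientations,
        fiber_endpoints=endpoints,
        cell_centroids=[(cy, cx) for cy, cx, *_ in cells],
        mu=spec.mu,
        kappa=spec.kappa,
    )
    return img, gt


def default_kappa_profile(condition: ConditionLabel) -> float:
    """Map a condition to a generating concentration.

    Confluent monolayers under flow align progressively: a Hill-type curve
    kappa(t) = kappa_max * t^2 / (t^2 + t50^2) with kappa_max = 2.5 and
    t50 = 6 h gives essentially no alignment at 1 h and strong alignment by
    24 h.  Sparse and static conditions get kappa = 0.  The exact profile
    is illustrative: the source analysis reports alignment graphically, not
    numerically.
    """
    if condition.density != "confluent" or condition.exposure != "LSS":
        return 0.0
    t = condition.duration_h
    return 2.5 * t**2 / (t**2 + 6.0**2)


def default_design(
    cell_type: str = "HUVEC",
    durations: Sequence[float] = (1.0, 6.0, 24.0),
    n_replicates: int = 3,
    shear_dyn_cm2: float = 15.0,
) -> list[ConditionLabel]:
    """The default factorial design: {static, LSS at each duration} x
    {confluent, sparse} x replicates."""
    design = []
    for density in ("confluent", "sparse"):
        for rep in range(1, n_replicates + 1):
            design.append(
                ConditionLabel(cell_type, density, "static", 0.0, shear_dyn_cm2, rep)
            )
            for t in durations:
                design.append(
                    ConditionLabel(cell_type, density, "LSS", t, shear_dyn_cm2, rep)
                )
    return design


def _item_seed(base_seed: int, condition: ConditionLabel) -> int:
    """Stable per-item seed from a hash of the condition key.

    Independent of design order so adding/removing conditions never changes
    another item's image.
    """
    key = (
        f"{base_seed}|{condition.cell_type}|{condition.density}|"
        f"{condition.exposure}|{condition.duration_h:g}|{condition.replicate}"
    )
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def generate_experiment(
    design: Sequence[ConditionLabel],
    template: SyntheticSpec,
    base_seed: int,
    out_dir: str | Path,
    kappa_profile=default_kappa_profile,
    mu: float = 0.0,
    sparse_coverage: float = 0.10,
) -> pd.DataFrame:
    """Render one image per (condition, replicate) and write a manifest.

    Each item gets a deterministic seed derived from ``base_seed`` and the
    condition key.  Images are written as 16-bit grayscale TIFF with a JSON
    ground-truth sidecar; the manifest CSV maps files to conditions and
    generating parameters.  Returns the manifest as a DataFrame.
    """
    if not design:
        raise ValueError("design must be non-empty")
    keys = [c.key() for c in design]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (condition, replicate) keys in design")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cond in design:
        kappa = float(kappa_profile(cond))
        layout = cond.density
        coverage = 1.0 if layout == "confluent" else min(sparse_coverage, 0.10)
        spec = replace(
            template,
            layout=layout,
            coverage_fraction=coverage,
            mu=mu,
            kappa=kappa,
            seed=_item_seed(base_seed, cond),
            condition=cond,
        )
        img, gt = render_image(spec)
        stem = (
            f"{cond.cell_type}_{cond.density}_{cond.level}_rep{cond.replicate}"
        )
        tif_path = out_dir / f"{stem}.tif"
        img16 = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        tifffile.imwrite(tif_path, img16)
        (out_dir / f"{stem}.gt.json").write_text(gt.to_json())
        rows.append(
            {
                "file": tif_path.name,
                "cell_type": cond.cell_type,
                "density": cond.density,
                "exposure": cond.exposure,
                "duration_h": cond.duration_h,
                "shear_dyn_cm2": cond.shear_dyn_cm2,
                "replicate": cond.replicate,
                "mu": mu,
                "kappa": kappa,
                "n_fibers": len(gt.true_orientations),
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def simulate_replicate_table(
    design: Sequence[ConditionLabel],
    base_seed: int,
    n_per_replicate: int = 2000,
    kappa_profile=default_kappa_profile,
    mu: float = 0.0,
    threshold_deg: float = 45.0,
) -> pd.DataFrame:
    """Simulate percent-aligned replicate tables without rendering images.

    Draws ``n_per_replicate`` axial orientations per (condition, replicate)
    directly from the generating distribution and applies the strict <45
    degree alignment rule.  Used for inference-level simulations (e.g.
    family-wise error calibration) where image rendering is irrelevant.
    """
    rows = []
    for cond in design:
        kappa = float(kappa_profile(cond))
        theta = sample_axial_orientations(
            n_per_replicate, mu, kappa, _item_seed(base_seed, cond)
        )
        dev = np.abs(theta - mu) % 180.0
        dev = np.minimum(dev, 180.0 - dev)
        pct = 100.0 * np.mean(dev < threshold_deg)
        rows.append(
            {
                "cell_type": cond.cell_type,
                "density": cond.density,
                "level": cond.level,
                "replicate": cond.replicate,
                "percent_aligned": pct,
            }
        )
    return pd.DataFrame(rows)
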