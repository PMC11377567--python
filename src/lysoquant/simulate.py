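"""Ground-truthed synthetic data for every input class of the pipeline.

The original acquisitions were not deposited, so each analysis stage is
exercised against generated data whose ground truth is known by
construction: fluorescence scenes with controllable puncta counts, radial
distribution, intensities and cross-channel colocalization; branched
filament networks with known junction counts; two-channel Laurdan images
with a known GP field; and Hertz-model force curves with known Young's
modulus and contact point.  All generators are deterministic given their
spec (which includes the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .actin import SkeletonGraph
from .afm import ForceCurve, TipModel, hertz_force
from .errors import CapacityError, DomainError
from .io import CellGeometry, Image2D, ImageStack, ResultTable

__all__ = [
    "SceneSpec",
    "NetworkSpec",
    "GPSpec",
    "CurveSpec",
    "simulate_scene",
    "simulate_network",
    "simulate_laurdan",
    "simulate_force_curve",
    "circle_polygon",
]


def circle_polygon(center: tuple[float, float], radius: float, n: int = 72) -> np.ndarray:
    """(x, y) vertex list of a regular polygon approximating a circle."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)])


# ---------------------------------------------------------------------------
# fluorescence scenes


@dataclass
class SceneSpec:
    """Specification of a multi-channel puncta scene.

    Puncta are placed in the cytoplasmic annulus between the nucleus and
    the cell outline.  ``beta`` biases the radial position: 0 is uniform
    over cytoplasmic area, values towards 1 enrich the periphery (the
    redistribution seen after lysosomal damage).  ``coloc[(a, b)] = rho``
    places exactly round(rho * n_b) channel-b puncta at channel-a
    centroids.  ``triple = (ref, p1, p2, frac)`` places one p1 and one p2
    punctum at round(frac * n_ref) reference centroids.
    """

    shape: tuple[int, int] = (256, 256)
    cell_radius: float = 100.0
    nucleus_radius: float = 30.0
    n_puncta: dict = field(default_factory=lambda: {"ch0": 50})
    beta: float = 0.0
    intensity_mean: float = 2000.0
    intensity_sd: float = 0.0
    coloc: dict = field(default_factory=dict)
    triple: tuple | None = None
    background: float = 10.0
    noise_sd: float = 0.0
    psf_sigma: float = 1.5
    min_separation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_radius < self.cell_radius:
            raise DomainError("need 0 < nucleus_radius < cell_radius")
        if not 0.0 <= self.beta <= 1.0:
            raise DomainError("beta must lie in [0, 1]")
        for pair, rho in self.coloc.items():
            if not 0.0 <= rho <= 1.0:
                raise DomainError(f"coloc fraction for {pair} must lie in [0, 1]")
        if any(n < 0 for n in self.n_puncta.values()):
            raise DomainError("puncta counts must be >= 0")

    @property
    def center(self) -> tuple[float, float]:
        return (self.shape[1] / 2.0, self.shape[0] / 2.0)


def _radial_quantile(u: np.ndarray, beta: float, rn: float, rc: float) -> np.ndarray:
    """Inverse-CDF sample of the radial fraction f on [0, 1].

    Density in f is proportional to ((1 - beta) + beta * f) * r(f) with
    r(f) = rn + f * (rc - rn): the beta weight applied to the annulus area
    element, so beta = 0 is exactly uniform over cytoplasmic area.
    """
    grid = np.linspace(0.0, 1.0, 2049)
    w = ((1 - beta) + beta * grid) * (rn + grid * (rc - rn))
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2)])
    cdf /= cdf[-1]
    return np.interp(u, cdf, grid)


def _place_independent(
    rng: np.random.Generator,
    n: int,
    spec: SceneSpec,
    existing: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n cytoplasmic positions honouring min_separation; returns (xy, f)."""
    cx, cy = spec.center
    rn, rc = spec.nucleus_radius, spec.cell_radius
    placed = list(existing)
    out_xy, out_f = [], []
    attempts_left = 2000 * max(n, 1)
    while len(out_xy) < n:
        if attempts_left <= 0:
            raise CapacityError(
                f"cannot place {n} puncta with min_separation={spec.min_separation}"
            )
        attempts_left -= 1
        f = float(_radial_quantile(rng.random(1), spec.beta, rn, rc)[0])
        theta = rng.uniform(0, 2 * np.pi)
        r = rn + f * (rc - rn)
        p = np.array([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        if spec.min_separation > 0 and placed:
            d = np.min(np.hypot(*(np.array(placed) - p).T))
            if d < spec.min_separation:
                continue
        placed.append(p)
        out_xy.append(p)
        out_f.append(f)
    return np.array(out_xy).reshape(-1, 2), np.array(out_f)


def _render_channel(spec: SceneSpec, xy: np.ndarray, intensities: np.ndarray,
                    rng: np.random.Generator, name: str) -> Image2D:
    h, w = spec.shape
    img = np.full((h, w), float(spec.background))
    sig = spec.psf_sigma
    half = int(np.ceil(4 * sig))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    for (x, y), inten in zip(xy, intensities):
        amp = inten / (2 * np.pi * sig**2)
        cx, cy = int(round(x)), int(round(y))
        spot = amp * np.exp(-(((xx + cx - x) ** 2) + ((yy + cy - y) ** 2)) / (2 * sig**2))
        r0, r1 = cy - half, cy + half + 1
        c0, c1 = cx - half, cx + half + 1
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r1, h), min(c1, w)
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        img[rr0:rr1, cc0:cc1] += spot[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, img.shape)
    return Image2D(np.clip(img, 0, None), channel_name=name)


def simulate_scene(spec: SceneSpec) -> tuple[ImageStack, CellGeometry, ResultTable]:
    """Render a multi-channel puncta scene with a per-punctum truth table.

    Truth columns: channel, punctum id, (x, y) centroid, integrated
    intensity, radial fraction, and the id of the punctum it was
    deliberately colocalized with (empty when placed independently).
    """
    rng = np.random.default_rng(spec.seed)
    rn, rc = spec.nucleus_radius, spec.cell_radius
    annulus_area = np.pi * (rc**2 - rn**2)
    total = sum(spec.n_puncta.values())
    if spec.min_separation > 0:
        # packing feasibility matters only when spots must not touch;
        # overlapping placements are legitimate for distribution statistics
        footprint = max(np.pi * (2 * spec.psf_sigma) ** 2, spec.min_separation**2)
        if total * footprint > annulus_area:
            raise CapacityError(
                f"{total} puncta at footprint {footprint:.1f} px^2 exceed the "
                f"cytoplasmic area {annulus_area:.1f} px^2"
            )

    geometry = CellGeometry(
        circle_polygon(spec.center, rc),
        circle_polygon(spec.center, rn),
        cell_id="sim0",
    )

    rows: list[dict] = []
    centroids: dict[str, np.ndarray] = {}
    fractions: dict[str, np.ndarray] = {}
    all_independent: list[np.ndarray] = []
    next_id = 0

    triple = spec.triple
    triple_idx: np.ndarray | None = None
    if triple is not None:
        ref_ch, _, _, frac = triple
        n_ref = spec.n_puncta.get(ref_ch, 0)
        # the same reference subset hosts both partner channels, so the
        # triple-positive fraction of the reference is frac by construction
        triple_idx = np.random.default_rng(spec.seed + 1).permutation(n_ref)[
            : int(round(frac * n_ref))
        ]
    for ch in spec.n_puncta:
        n = spec.n_puncta[ch]
        partner_ids = [""] * n
        pair = next((p for p in spec.coloc if p[1] == ch and p[0] in centroids), None)
        xy = np.empty((n, 2))
        fr = np.empty(n)
        k = 0
        if pair is not None:
            rho = spec.coloc[pair]
            k = int(round(rho * n))
            src = centroids[pair[0]]
            idx = rng.choice(len(src), size=k, replace=k > len(src))
            xy[:k] = src[idx]
            fr[:k] = fractions[pair[0]][idx]
            src_ids = [r["punctum_id"] for r in rows if r["channel"] == pair[0]]
            for i, j in enumerate(idx):
                partner_ids[i] = src_ids[j]
        elif triple is not None and ch in (triple[1], triple[2]) and triple[0] in centroids:
            src = centroids[triple[0]]
            idx = triple_idx[: min(len(triple_idx), n)]
            k = len(idx)
            xy[:k] = src[idx]
            fr[:k] = fractions[triple[0]][idx]
            src_ids = [r["punctum_id"] for r in rows if r["channel"] == triple[0]]
            for i, j in enumerate(idx):
                partner_ids[i] = src_ids[j]
        if n - k > 0:
            pos, f = _place_independent(rng, n - k, spec, all_independent)
            xy[k:] = pos
            fr[k:] = f
            all_independent.extend(pos)
        elif n == 0:
            xy = np.empty((0, 2))
            fr = np.empty(0)
        intensities = np.clip(
            rng.normal(spec.intensity_mean, spec.intensity_sd, n), 1e-6, None
        ) if n else np.empty(0)
        centroids[ch] = xy
        fractions[ch] = fr
        for i in range(n):
            rows.append(
                {
                    "channel": ch,
                    "punctum_id": next_id,
                    "x": xy[i, 0],
                    "y": xy[i, 1],
                    "intensity": intensities[i],
                    "radial_fraction": fr[i],
                    "partner_of": partner_ids[i],
                }
            )
            next_id += 1

    planes = []
    for ch in spec.n_puncta:
        sub = [r for r in rows if r["channel"] == ch]
        xy = np.array([[r["x"], r["y"]] for r in sub]).reshape(-1, 2)
        inten = np.array([r["intensity"] for r in sub])
        planes.append(_render_channel(spec, xy, inten, rng, ch))
    stack = ImageStack(planes, axis="channel")
    truth = ResultTable(
        pd.DataFrame(rows, columns=[
            "channel", "punctum_id", "x", "y", "intensity", "radial_fraction", "partner_of",
        ]),
        provenance={"generator": "simulate_scene", "seed": spec.seed,
                    "parameters": {k: str(v) for k, v in vars(spec).items()}},
    )
    return stack, geometry, truth


# ---------------------------------------------------------------------------
# filament networks


@dataclass
class NetworkSpec:
    """Specification of a branched filament image.

    Junction motifs (a central node with 3 or 4 arms) and free filaments
    are placed on a grid with enough margin that they never merge; the
    truth graph has exactly the requested degree-3 and degree-4 node
    counts.  ``kappa`` concentrates motif orientations around 0 degrees
    (larger = more parallel network).
    """

    shape: tuple[int, int] = (256, 256)
    n_triple: int = 0
    n_quadruple: int = 0
    n_filaments: int = 0
    mean_branch_length: float = 20.0
    width: int = 3
    kappa: float = 0.0
    amplitude: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_triple, self.n_quadruple, self.n_filaments) < 0:
            raise DomainError("motif counts must be >= 0")
        if self.mean_branch_length < 2:
            raise DomainError("mean branch length must be >= 2 px")


def _truth_graph(motifs: list[tuple[np.ndarray, list[np.ndarray]]]) -> SkeletonGraph:
    g = nx.MultiGraph()
    nid = 0
    npx = 0
    for center, tips in motifs:
        if len(tips) == 2 and center is None:
            a, b = tips
            g.add_node(nid, pos=tuple(a), kind="endpoint")
            g.add_node(nid + 1, pos=tuple(b), kind="endpoint")
            length = float(np.hypot(*(b - a)))
            g.add_edge(nid, nid + 1, length=length, path=[])
            npx += int(length)
            nid += 2
        else:
            cid = nid
            g.add_node(cid, pos=tuple(center), kind="junction")
            nid += 1
            for tip in tips:
                g.add_node(nid, pos=tuple(tip), kind="endpoint")
                length = float(np.hypot(*(tip - center)))
                g.add_edge(cid, nid, length=length, path=[])
                npx += int(length)
                nid += 1
    return SkeletonGraph(g, npx)


def simulate_network(spec: NetworkSpec) -> tuple[Image2D, SkeletonGraph]:
    """Render a filament network image plus its ground-truth graph."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    margin = spec.mean_branch_length * 1.35 + spec.width + 4
    cell = 2 * margin
    nx_cells = int((w - 2 * spec.width) // cell)
    ny_cells = int((h - 2 * spec.width) // cell)
    n_motifs = spec.n_triple + spec.n_quadruple + spec.n_filaments
    if n_motifs > nx_cells * ny_cells:
        raise CapacityError(
            f"{n_motifs} motifs do not fit a {ny_cells}x{nx_cells} grid at "
            f"branch length {spec.mean_branch_length}"
        )
    slots = [
        np.array([spec.width + (i + 0.5) * cell, spec.width + (j + 0.5) * cell])
        for i in range(nx_cells)
        for j in range(ny_cells)
    ]
    order = rng.permutation(len(slots))[:n_motifs]

    kinds = ["triple"] * spec.n_triple + ["quadruple"] * spec.n_quadruple + [
        "filament"
    ] * spec.n_filaments
    canvas = np.zeros((h, w))
    motifs = []
    for kind, slot_idx in zip(kinds, order):
        center = slots[slot_idx] + rng.uniform(-2, 2, 2)
        base = rng.vonmises(0.0, spec.kappa) / 2.0 if spec.kappa > 0 else rng.uniform(0, np.pi)
        if kind == "filament":
            length = max(4.0, rng.normal(spec.mean_branch_length, 0.15 * spec.mean_branch_length))
            d = np.array([np.cos(base), np.sin(base)])
            a = center - d * length / 2
            b = center + d * length / 2
            segments = [(a, b)]
            motifs.append((None, [a, b]))
        else:
            n_arms = 3 if kind == "triple" else 4
            step = 2 * np.pi / n_arms
            tips = []
            segments = []
            for i in range(n_arms):
                ang = base + i * step + rng.uniform(-0.15, 0.15)
                length = max(4.0, rng.normal(spec.mean_branch_length, 0.15 * spec.mean_branch_length))
                tip = center + length * np.array([np.cos(ang), np.sin(ang)])
                tips.append(tip)
                segments.append((center, tip))
            motifs.append((center, tips))
        for a, b in segments:
            rr, cc = draw_line(
                int(round(a[1])), int(round(a[0])), int(round(b[1])), int(round(b[0]))
            )
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            canvas[rr[ok], cc[ok]] = 1.0

    if spec.width > 1:
        canvas = dilation(canvas, disk(spec.width // 2))
    img = gaussian_filter(canvas * spec.amplitude, 0.7)
    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, img.shape)
    return Image2D(np.clip(img, 0, None), channel_name="phalloidin"), _truth_graph(motifs)


# ---------------------------------------------------------------------------
# Laurdan two-channel images


@dataclass
class GPSpec:
    """Specification of a two-channel Laurdan acquisition.

    ``gp_field`` is the true per-pixel GP (scalar or array in [-1, 1]);
    ``total_field`` the per-pixel summed calibrated intensity T.  Channels
    are emitted so that the GP equation with factor ``g_factor`` returns
    the field exactly at zero noise.
    """

    shape: tuple[int, int] = (64, 64)
    gp_field: float | np.ndarray = 0.0
    g_factor: float = 1.0
    total_field: float | np.ndarray = 200.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        gp = np.asarray(self.gp_field, float)
        if gp.min() < -1 or gp.max() > 1:
            raise DomainError("GP field must lie within [-1, 1]")
        if self.g_factor <= 0:
            raise DomainError("G factor must be positive")


def simulate_laurdan(spec: GPSpec) -> tuple[Image2D, Image2D]:
    """Emit the blue (400-460 nm) and red (470-530 nm) Laurdan channels.

    Per pixel with total T and true gp: I_blue = T (1 + gp) / 2 and
    I_red = T (1 - gp) / (2 G), the exact inverse of the GP equation.
    """
    rng = np.random.default_rng(spec.seed)
    gp = np.broadcast_to(np.asarray(spec.gp_field, float), spec.shape).copy()
    total = np.broadcast_to(np.asarray(spec.total_field, float), spec.shape).copy()
    blue = total * (1 + gp) / 2.0
    red = total * (1 - gp) / (2.0 * spec.g_factor)
    if spec.noise_sd > 0:
        blue = blue + rng.normal(0, spec.noise_sd, spec.shape)
        red = red + rng.normal(0, spec.noise_sd, spec.shape)
    return (
        Image2D(np.clip(blue, 0, None), channel_name="I400-460"),
        Image2D(np.clip(red, 0, None), channel_name="I470-530"),
    )


# ---------------------------------------------------------------------------
# AFM force curves


@dataclass
class CurveSpec:
    """Specification of a synthetic Hertz-model approach curve.

    Defaults mirror the original acquisition: pyramidal silicon-nitride
    tip, 0.02 N/m cantilever, 500 pN maximum applied force.  The force is
    zero until contact at ``contact_point_nm`` and then follows the Hertz
    model with indentation corrected for cantilever deflection.
    """

    youngs_modulus_pa: float = 5000.0
    poisson_ratio: float = 0.5
    tip: TipModel = field(default_factory=TipModel)
    contact_point_nm: float = 0.0
    spacing_nm: float = 5.0
    max_force_pn: float = 500.0
    baseline_nm: float = 500.0
    spring_constant: float = 0.02
    noise_sd_pn: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.youngs_modulus_pa <= 0:
            raise DomainError("Young's modulus must be positive")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise DomainError("Poisson ratio must lie in [0, 0.5]")
        if self.max_force_pn <= 0:
            raise DomainError("max force must be positive")

    @property
    def max_indentation_nm(self) -> float:
        """Indentation depth at the maximum applied force (truth value)."""
        c = self.tip.prefactor(self.youngs_modulus_pa, self.poisson_ratio)
        return float((self.max_force_pn / c) ** (1.0 / self.tip.exponent))


def simulate_force_curve(spec: CurveSpec) -> ForceCurve:
    """Generate one seed-deterministic approach force-distance curve."""
    rng = np.random.default_rng(spec.seed)
    k = spec.spring_constant * 1e3  # pN/nm
    z0 = spec.contact_point_nm
    travel = spec.max_indentation_nm + spec.max_force_pn / k
    z = np.arange(z0 + spec.baseline_nm, z0 - travel - spec.spacing_nm, -spec.spacing_nm)
    forces = np.zeros_like(z)
    c = spec.tip.prefactor(spec.youngs_modulus_pa, spec.poisson_ratio)
    m = spec.tip.exponent
    for i, zi in enumerate(z):
        if zi >= z0:
            continue
        ramp = z0 - zi  # piezo travel past contact = delta + F/k

        def resid(f):
            return c * max(ramp - f / k, 0.0) ** m - f

        forces[i] = brentq(resid, 0.0, c * ramp**m + 1.0)
    if spec.noise_sd_pn > 0:
        forces = forces + rng.normal(0, spec.noise_sd_pn, forces.shape)
    return ForceCurve(z, forces, spring_constant=spec.spring_constant)
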