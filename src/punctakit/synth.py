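"""Synthetic fluorescence scenes with known ground truth.

Generates two-channel (nuclei + aggregate, optionally + mRNA) scenes that
emulate intranuclear protein-aggregate puncta of two phenotypes:

* "ala10-like" — fewer, smaller, rounder, slower puncta with lower peak
  intensity and lower mRNA co-sequestration (benign aggregates);
* "ala16-like" — more, larger, multi-lobed/irregular, faster puncta with
  higher peak intensity and higher mRNA co-sequestration (pathogenic
  aggregates).

Puncta are unions of 1..k offset disks: a single disk gives a near-circular
punctum, several overlapping disks give a "bouquet"-like irregular blob with
controllably reduced circularity.  Nuclei are non-overlapping ellipses.
Time-lapse mobility is Brownian: per-frame Gaussian displacements with
per-axis variance 2*D*dt, reflected at the nucleus boundary.  Noise is
optional Poisson (photon) noise on the signal followed by additive Gaussian
(readout) noise.  All randomness flows from one integer seed through one
``numpy.random.Generator``; identical seed + params give bit-identical
output.

The absolute size/intensity scales are calibration choices (no reference
distributions exist for the real data); they are documented in the methods
note and fixed in the two presets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import perimeter_crofton
from skimage.segmentation import expand_labels

from .io import Scene

logger = logging.getLogger(__name__)


class GeometryError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


@dataclass
class NoiseModel:
    gaussian_sd: float = 4.0
    poisson: bool = True


@dataclass
class PhenotypeParams:
    """Knobs of one synthetic phenotype.

    Lengths are in micrometres, intensities in arbitrary camera units,
    diffusion in um^2/s.  ``n_lobes_range=(1, 1)`` produces circular puncta;
    wider ranges produce multi-lobed irregular blobs.
    """

    n_nuclei: int = 3
    puncta_per_nucleus_mean: float = 3.0
    punctum_radius_um_mean: float = 0.32
    punctum_radius_um_sd: float = 0.06
    n_lobes_range: tuple[int, int] = (1, 1)
    punctum_peak_intensity_mean: float = 500.0
    punctum_peak_intensity_sd: float = 60.0
    diffusion_coeff_um2_per_s: float = 0.005
    mrna_coloc_fraction: float = 0.25
    background_mean: float = 10.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    # rendering/geometry details
    edge_sigma_px: float = 0.5
    nucleus_semiaxis_a_um: tuple[float, float] = (4.0, 4.6)
    nucleus_semiaxis_b_um: tuple[float, float] = (3.3, 3.9)
    nucleus_intensity: float = 300.0
    mrna_mean_intensity: float = 100.0
    mrna_cytoplasm_fraction: float = 0.3
    ring_width_um: float = 2.0

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.puncta_per_nucleus_mean < 0:
            raise ValueError("puncta_per_nucleus_mean must be >= 0")
        if min(self.punctum_radius_um_mean, self.punctum_radius_um_sd) <= 0:
            raise ValueError("punctum radius mean/sd must be > 0")
        lo, hi = self.n_lobes_range
        if lo < 1 or hi < lo:
            raise ValueError("n_lobes_range must be an increasing pair >= (1, 1)")
        if not 0.0 <= self.mrna_coloc_fraction <= 1.0:
            raise ValueError("mrna_coloc_fraction must be in [0, 1]")
        if self.diffusion_coeff_um2_per_s < 0:
            raise ValueError("diffusion_coeff_um2_per_s must be >= 0")


#: Documented phenotype presets (calibration choices, see docs/methods.md).
PRESETS: dict[str, PhenotypeParams] = {
    "ala10": PhenotypeParams(
        n_nuclei=3,
        puncta_per_nucleus_mean=3.0,
        punctum_radius_um_mean=0.32,
        punctum_radius_um_sd=0.06,
        n_lobes_range=(1, 1),
        punctum_peak_intensity_mean=500.0,
        punctum_peak_intensity_sd=60.0,
        diffusion_coeff_um2_per_s=0.005,
        mrna_coloc_fraction=0.25,
    ),
    "ala16": PhenotypeParams(
        n_nuclei=3,
        puncta_per_nucleus_mean=7.0,
        punctum_radius_um_mean=0.38,
        punctum_radius_um_sd=0.10,
        n_lobes_range=(2, 5),
        punctum_peak_intensity_mean=950.0,
        punctum_peak_intensity_sd=120.0,
        diffusion_coeff_um2_per_s=0.04,
        mrna_coloc_fraction=0.60,
    ),
}

DEFAULT_SHAPE = (288, 288)
DEFAULT_PIXEL_SIZE_UM = 0.1


def preset(name: str, seed: Optional[int] = None, **overrides) -> PhenotypeParams:
    """Return a copy of a named preset, optionally reseeded/overridden."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    if seed is not None:
        overrides["seed"] = seed
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Per-scene ground truth for every generated object.

    ``puncta`` has one row per punctum (frame-0 geometry of the noiseless
    binary blob); ``tracks`` has one row per punctum per frame with the true
    centre in micrometres.  ``puncta_labels``/``nuclei_labels`` are the true
    frame-0 label masks.
    """

    nuclei: pd.DataFrame
    puncta: pd.DataFrame
    tracks: pd.DataFrame
    nuclei_labels: np.ndarray
    puncta_labels: np.ndarray
    pixel_size_um: float
    diffusion_coeff_um2_per_s: float
    mrna_coloc_fraction: Optional[float] = None
    mrna_per_nucleus: Optional[pd.DataFrame] = None


# ----------------------------------------------------------------------
# geometry helpers


def _rasterize_ellipse(shape, center, a_px, b_px, theta) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    cos, sin = np.cos(theta), np.sin(theta)
    u = (dr * cos + dc * sin) / a_px
    v = (-dr * sin + dc * cos) / b_px
    return u * u + v * v <= 1.0


def _rasterize_disks(shape, centers_px, radii_px) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for (r0, c0), rad in zip(centers_px, radii_px):
        lo_r = max(int(np.floor(r0 - rad)) - 1, 0)
        hi_r = min(int(np.ceil(r0 + rad)) + 2, shape[0])
        lo_c = max(int(np.floor(c0 - rad)) - 1, 0)
        hi_c = min(int(np.ceil(c0 + rad)) + 2, shape[1])
        if lo_r >= hi_r or lo_c >= hi_c:
            continue
        rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        mask[lo_r:hi_r, lo_c:hi_c] |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    return mask


def _blob_circularity(mask: np.ndarray) -> float:
    area = int(mask.sum())
    if area == 0:
        return np.nan
    perim = perimeter_crofton(mask, directions=4)
    if perim == 0:
        return 1.0
    return float(min(1.0, 4.0 * np.pi * area / perim**2))


def _place_nuclei(rng, params: PhenotypeParams, shape, ps: float):
    """Place non-overlapping ellipses; raise GeometryError if impossible."""
    for _restart in range(4):
        nuclei = []
        ok = True
        for _ in range(params.n_nuclei):
            a_um = rng.uniform(*params.nucleus_semiaxis_a_um)
            b_um = rng.uniform(*params.nucleus_semiaxis_b_um)
            theta = rng.uniform(0, np.pi)
            rb_um = max(a_um, b_um) + 0.2
            rb_px = rb_um / ps
            if rb_px + 2 >= min(shape) - rb_px - 2:
                raise GeometryError(
                    f"nucleus of bounding radius {rb_um:.1f} um does not fit a "
                    f"{shape[0]}x{shape[1]} image at {ps} um/px"
                )
            placed = False
            for _try in range(400):
                r0 = rng.uniform(rb_px + 2, shape[0] - rb_px - 2)
                c0 = rng.uniform(rb_px + 2, shape[1] - rb_px - 2)
                if all(
                    np.hypot(r0 - n["r"], c0 - n["c"]) * ps
                    > rb_um + max(n["a"], n["b"]) + 0.4
                    for n in nuclei
                ):
                    nuclei.append({"r": r0, "c": c0, "a": a_um, "b": b_um, "t": theta})
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return nuclei
    raise GeometryError(
        f"could not place {params.n_nuclei} non-overlapping nuclei in a "
        f"{shape[0]}x{shape[1]} image at {ps} um/px"
    )


def _sample_blob_geometry(rng, params: PhenotypeParams, ps: float):
    """Sample one punctum blob: lobe offsets (um) and radii (um)."""
    radius = max(float(rng.normal(params.punctum_radius_um_mean, params.punctum_radius_um_sd)), 1.8 * ps)
    lo, hi = params.n_lobes_range
    n_lobes = int(rng.integers(lo, hi + 1))
    offsets = [(0.0, 0.0)]
    radii = [radius]
    for _ in range(n_lobes - 1):
        ang = rng.uniform(0, 2 * np.pi)
        dist = radius * rng.uniform(0.9, 1.5)
        offsets.append((dist * np.cos(ang), dist * np.sin(ang)))
        radii.append(radius * rng.uniform(0.5, 0.8))
    extent = max(np.hypot(*off) + rad for off, rad in zip(offsets, radii))
    return n_lobes, offsets, radii, float(extent)


def _inside_point(rng, nuc, extent_um: float, ps: float):
    """Uniform point in the nucleus ellipse shrunk by the blob extent (px)."""
    a_eff = max(nuc["a"] - extent_um, 0.3)
    b_eff = max(nuc["b"] - extent_um, 0.3)
    u = rng.uniform(0, 1)
    ang = rng.uniform(0, 2 * np.pi)
    rad = np.sqrt(u)
    x = a_eff * rad * np.cos(ang)
    y = b_eff * rad * np.sin(ang)
    cos, sin = np.cos(nuc["t"]), np.sin(nuc["t"])
    dr = (x * cos - y * sin) / ps
    dc = (x * sin + y * cos) / ps
    return nuc["r"] + dr, nuc["c"] + dc


def _reflect_into_ellipse(nuc, extent_um, ps, r, c):
    """Radially reflect a pixel-space point back inside the shrunk ellipse."""
    a_eff = max(nuc["a"] - extent_um, 0.3)
    b_eff = max(nuc["b"] - extent_um, 0.3)
    cos, sin = np.cos(nuc["t"]), np.sin(nuc["t"])
    dr = (r - nuc["r"]) * ps
    dc = (c - nuc["c"]) * ps
    x = dr * cos + dc * sin
    y = -dr * sin + dc * cos
    rho = np.hypot(x / a_eff, y / b_eff)
    if rho > 1.0:
        rho_new = max(2.0 - rho, 0.0) if rho < 2.0 else np.mod(rho, 1.0)
        scale = rho_new / rho if rho > 0 else 0.0
        x *= scale
        y *= scale
    dr = x * cos - y * sin
    dc = x * sin + y * cos
    return nuc["r"] + dr / ps, nuc["c"] + dc / ps


# ----------------------------------------------------------------------
# rendering


def _apply_noise(rng, img: np.ndarray, noise: NoiseModel) -> np.ndarray:
    out = img
    if noise.poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _render_aggregate(shape, puncta_rows, masks, edge_sigma, background):
    signal = np.zeros(shape, dtype=np.float64)
    for row, mask in zip(puncta_rows, masks):
        np.maximum(signal, mask * row["peak_intensity"], out=signal)
    if edge_sigma > 0:
        signal = ndi.gaussian_filter(signal, edge_sigma)
    return signal + background


def _build(params: PhenotypeParams, image_shape, pixel_size_um, n_frames, frame_interval_s):
    ps = float(pixel_size_um)
    shape = tuple(int(v) for v in image_shape)
    rng = np.random.default_rng(params.seed)

    nuclei = _place_nuclei(rng, params, shape, ps)
    nuclei_labels = np.zeros(shape, dtype=np.int32)
    nuc_rows = []
    for i, nuc in enumerate(nuclei, start=1):
        ell = _rasterize_ellipse(shape, (nuc["r"], nuc["c"]), nuc["a"] / ps, nuc["b"] / ps, nuc["t"])
        nuclei_labels[ell & (nuclei_labels == 0)] = i
        nuc_rows.append(
            {
                "nucleus_id": i,
                "center_row_px": nuc["r"],
                "center_col_px": nuc["c"],
                "semiaxis_a_um": nuc["a"],
                "semiaxis_b_um": nuc["b"],
                "theta_rad": nuc["t"],
                "cell_id": i,
            }
        )

    # --- sample puncta ------------------------------------------------
    puncta_rows = []
    blob_geoms = []  # (nucleus dict, offsets_um, radii_um, extent, center per frame)
    pid = 0
    for i, nuc in enumerate(nuclei, start=1):
        count = int(rng.poisson(params.puncta_per_nucleus_mean))
        placed_centers: list[tuple[float, float, float]] = []
        for _ in range(count):
            n_lobes, offsets, radii, extent = _sample_blob_geometry(rng, params, ps)
            peak = max(
                float(rng.normal(params.punctum_peak_intensity_mean, params.punctum_peak_intensity_sd)),
                1.0,
            )
            overlaps = False
            for attempt in range(60):
                r0, c0 = _inside_point(rng, nuc, extent, ps)
                if all(
                    np.hypot(r0 - pr, c0 - pc) * ps > extent + pe + 0.1
                    for pr, pc, pe in placed_centers
                ):
                    break
            else:
                overlaps = True
                r0, c0 = _inside_point(rng, nuc, extent, ps)
            placed_centers.append((r0, c0, extent))
            pid += 1
            puncta_rows.append(
                {
                    "punctum_id": pid,
                    "nucleus_id": i,
                    "n_lobes": n_lobes,
                    "base_radius_um": radii[0],
                    "peak_intensity": peak,
                    "plateau_intensity": peak + params.background_mean,
                    "overlaps": overlaps,
                }
            )
            blob_geoms.append({"nuc": nuc, "offsets": offsets, "radii": radii, "extent": extent, "center0": (r0, c0)})

    # --- diffuse centres over frames ---------------------------------
    step_sd_um = (
        np.sqrt(2.0 * params.diffusion_coeff_um2_per_s * frame_interval_s)
        if (n_frames > 1 and frame_interval_s)
        else 0.0
    )
    centers = np.zeros((len(blob_geoms), n_frames, 2), dtype=np.float64)  # px
    for j, geom in enumerate(blob_geoms):
        r, c = geom["center0"]
        centers[j, 0] = (r, c)
        for t in range(1, n_frames):
            if step_sd_um > 0:
                dr, dc = rng.normal(0.0, step_sd_um / ps, size=2)
                r, c = _reflect_into_ellipse(geom["nuc"], geom["extent"], ps, r + dr, c + dc)
            centers[j, t] = (r, c)

    # --- rasterize frame-0 truth --------------------------------------
    puncta_labels = np.zeros(shape, dtype=np.int32)
    frame0_masks = []
    for row, geom, ctr in zip(puncta_rows, blob_geoms, centers[:, 0]):
        disk_centers = [
            (ctr[0] + off[0] / ps, ctr[1] + off[1] / ps) for off in geom["offsets"]
        ]
        mask = _rasterize_disks(shape, disk_centers, [rad / ps for rad in geom["radii"]])
        frame0_masks.append(mask)
        puncta_labels[mask] = row["punctum_id"]
        row["area_px"] = int(mask.sum())
        row["area_um2"] = row["area_px"] * ps * ps
        row["circularity"] = _blob_circularity(mask)

    tracks = pd.DataFrame(
        {
            "punctum_id": np.repeat([r["punctum_id"] for r in puncta_rows], n_frames),
            "frame": np.tile(np.arange(n_frames), len(puncta_rows)),
            "row_um": (centers[:, :, 0] * ps).ravel(),
            "col_um": (centers[:, :, 1] * ps).ravel(),
        }
        if puncta_rows
        else {"punctum_id": [], "frame": [], "row_um": [], "col_um": []}
    )

    # --- render channels ----------------------------------------------
    nuc_signal = ndi.gaussian_filter((nuclei_labels > 0) * params.nucleus_intensity, 1.0)
    frames = np.zeros((n_frames, 2) + shape, dtype=np.float32)
    for t in range(n_frames):
        if t == 0:
            masks_t = frame0_masks
        else:
            masks_t = []
            for geom, ctr in zip(blob_geoms, centers[:, t]):
                disk_centers = [
                    (ctr[0] + off[0] / ps, ctr[1] + off[1] / ps) for off in geom["offsets"]
                ]
                masks_t.append(
                    _rasterize_disks(shape, disk_centers, [rad / ps for rad in geom["radii"]])
                )
        agg = _render_aggregate(
            shape, puncta_rows, masks_t, params.edge_sigma_px, params.background_mean
        )
        frames[t, 0] = _apply_noise(rng, nuc_signal + params.background_mean, params.noise_model)
        frames[t, 1] = _apply_noise(rng, agg, params.noise_model)

    scene = Scene(
        pixels=frames,
        channel_names=["nuclei", "aggregate"],
        pixel_size_um=ps,
        frame_interval_s=frame_interval_s if n_frames > 1 else None,
        bit_depth=16,
    )
    truth = GroundTruth(
        nuclei=pd.DataFrame(nuc_rows),
        puncta=pd.DataFrame(puncta_rows),
        tracks=tracks,
        nuclei_labels=nuclei_labels,
        puncta_labels=puncta_labels,
        pixel_size_um=ps,
        diffusion_coeff_um2_per_s=params.diffusion_coeff_um2_per_s,
    )
    return scene, truth


def generate_scene(
    params: PhenotypeParams,
    image_shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[Scene, GroundTruth]:
    """Generate a single-frame two-channel scene with ground truth."""
    return _build(params, image_shape, pixel_size_um, n_frames=1, frame_interval_s=None)


def generate_timelapse(
    params: PhenotypeParams,
    n_frames: int,
    frame_interval_s: float,
    image_shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[Scene, GroundTruth]:
    """Generate a time-lapse with Brownian punctum motion.

    Per-frame displacements are Gaussian with per-axis variance
    ``2 * D * frame_interval_s`` (um^2), reflected at the nucleus boundary
    so every punctum stays fully intranuclear.
    """
    if n_frames < 3:
        raise ValueError("a time-lapse needs n_frames >= 3")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be > 0")
    return _build(params, image_shape, pixel_size_um, n_frames, frame_interval_s)


def generate_mrna_channel(
    scene: Scene, truth: GroundTruth, params: PhenotypeParams
) -> tuple[Scene, GroundTruth]:
    """Append an "mrna" channel whose punctum-localized share of the total
    (noiseless) probe signal equals ``params.mrna_coloc_fraction``.

    The budget is per nucleus: within each nucleus a fraction f of the probe
    intensity is uniform over that nucleus's true puncta, the remainder is
    diffuse, split between the nucleus interior and a perinuclear ring by
    ``mrna_cytoplasm_fraction``.  The diffuse term covers punctum pixels too
    (soluble mRNA pervades the nucleoplasm), so the realized punctum-mask
    share is f plus a small positive rasterization term, recorded per
    nucleus in the returned ground truth.
    """
    f = params.mrna_coloc_fraction
    if not 0.0 <= f <= 1.0:
        raise ValueError("mrna_coloc_fraction must be in [0, 1]")
    if scene.has_channel("mrna"):
        raise ValueError("scene already has an mrna channel")
    ps = scene.pixel_size_um
    shape = scene.shape
    rng = np.random.default_rng((params.seed + 987654321) % (2**31))

    ring_px = max(int(round(params.ring_width_um / ps)), 1)
    expanded = expand_labels(truth.nuclei_labels, distance=ring_px)

    base = np.zeros(shape, dtype=np.float64)
    localized = np.zeros(shape, dtype=np.float64)
    per_nuc = []
    for _, nuc in truth.nuclei.iterrows():
        i = int(nuc["nucleus_id"])
        nuc_mask = truth.nuclei_labels == i
        ring_mask = (expanded == i) & ~(truth.nuclei_labels > 0)
        punc_mask = np.isin(
            truth.puncta_labels,
            truth.puncta.loc[truth.puncta["nucleus_id"] == i, "punctum_id"].to_numpy(),
        ) if len(truth.puncta) else np.zeros(shape, bool)
        n_nuc, n_ring, n_punc = nuc_mask.sum(), ring_mask.sum(), punc_mask.sum()
        total = params.mrna_mean_intensity * (n_nuc + n_ring)
        f_eff = f if n_punc > 0 else 0.0
        if f > 0 and n_punc == 0:
            logger.warning("nucleus %d has no puncta; mRNA made fully diffuse", i)
        cf = params.mrna_cytoplasm_fraction
        if n_punc:
            localized[punc_mask] += f_eff * total / n_punc
        if n_nuc:
            base[nuc_mask] += (1 - f_eff) * (1 - cf) * total / n_nuc
        if n_ring:
            base[ring_mask] += (1 - f_eff) * cf * total / n_ring
        per_nuc.append(
            {
                "nucleus_id": i,
                "target_fraction": f_eff,
                "realized_fraction": (
                    float(
                        (
                            f_eff * total
                            + (1 - f_eff) * (1 - cf) * total * n_punc / max(n_nuc, 1)
                        )
                        / total
                    )
                    if total > 0
                    else np.nan
                ),
            }
        )

    if params.edge_sigma_px > 0:
        localized = ndi.gaussian_filter(localized, params.edge_sigma_px)
    noiseless = base + localized + params.background_mean

    mrna_frames = np.stack(
        [
            _apply_noise(rng, noiseless, params.noise_model)
            for _ in range(scene.n_frames)
        ]
    ).astype(np.float32)

    pixels = np.concatenate([scene.pixels, mrna_frames[:, np.newaxis]], axis=1)
    new_scene = Scene(
        pixels=pixels,
        channel_names=list(scene.channel_names) + ["mrna"],
        pixel_size_um=scene.pixel_size_um,
        frame_interval_s=scene.frame_interval_s,
        bit_depth=scene.bit_depth,
        name=scene.name,
    )
    truth.mrna_coloc_fraction = f
    truth.mrna_per_nucleus = pd.DataFrame(per_nuc)
    return new_scene, truth
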