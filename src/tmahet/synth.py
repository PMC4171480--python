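"""Synthetic TMA-like images and survival cohorts with ground truth.

Cells are rendered as elliptical nuclei inside larger concentric
elliptical cytoplasms — the "small round cell" morphology of Ewing
sarcoma — so every compartment mean has an analytic ground truth.  A
configurable fraction of cells is planted as a prognostic subpopulation
(Ki67-positive / CD99-low by default) and patient survival is drawn from
a proportional-hazards model on the planted per-patient fraction, which
makes the whole downstream chain (segmentation -> features -> survival
models) testable without any external image download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from tmahet.types import MultiChannelImage, SurvivalRecord

# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ChannelModel:
    """Compartment intensity model for one fluorescence channel.

    Per-cell compartment means are drawn as
    ``Normal(mean, cell_sd)`` truncated at ``min_intensity`` so cells
    differ from one another; within a cell the noiseless compartment is
    flat (noise is added image-wide afterwards).
    """

    nuclear_mean: float
    cytoplasm_mean: float
    cell_sd: float = 0.0
    min_intensity: float = 1.0


def default_channel_models() -> dict[str, ChannelModel]:
    """Baseline (non-subpopulation) intensity models for the four channels."""
    return {
        "DAPI": ChannelModel(nuclear_mean=180.0, cytoplasm_mean=20.0, cell_sd=15.0),
        "CD99": ChannelModel(nuclear_mean=30.0, cytoplasm_mean=120.0, cell_sd=10.0),
        "Ki67": ChannelModel(nuclear_mean=30.0, cytoplasm_mean=60.0, cell_sd=8.0),
    }


def default_subpop_channel_models() -> dict[str, ChannelModel]:
    """Planted prognostic subpopulation: Ki67-positive (high nuclear Ki67,
    log2 N/C ratio > 0) and CD99-low (cytoplasmic CD99 below nuclear)."""
    return {
        "DAPI": ChannelModel(nuclear_mean=180.0, cytoplasm_mean=20.0, cell_sd=15.0),
        "CD99": ChannelModel(nuclear_mean=30.0, cytoplasm_mean=22.0, cell_sd=5.0),
        "Ki67": ChannelModel(nuclear_mean=120.0, cytoplasm_mean=40.0, cell_sd=10.0),
    }


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of one rendered multi-channel image.

    ``overlap_fraction`` is the proportion of cells deliberately placed
    against an already-placed cell (clumps of 2-3) by relaxing the
    minimum centre-distance constraint; the remaining cells are kept
    disjoint.  512 px is the desk-scale default; the real acquisition
    scale (2048 px, 211 um field) is reached by setting ``image_size``
    and ``pixel_size`` accordingly.
    """

    image_size: int = 512
    n_cells: int = 60
    nucleus_radius_range: tuple[float, float] = (8.0, 13.0)
    cytoplasm_thickness_range: tuple[float, float] = (4.0, 8.0)
    overlap_fraction: float = 0.0
    eccentricity_max: float = 0.3
    channel_models: dict[str, ChannelModel] = field(
        default_factory=default_channel_models
    )
    subpop_channel_models: dict[str, ChannelModel] = field(
        default_factory=default_subpop_channel_models
    )
    subpop_fraction: float = 0.0
    background: float = 8.0
    noise_sigma: float = 0.0
    poisson_noise: bool = False
    blur_sigma: float = 0.0
    pixel_size: float = 211.0 / 2048.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.nucleus_radius_range[0] <= 0 or self.cytoplasm_thickness_range[0] <= 0:
            raise ValueError("radii and thicknesses must be positive")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur_sigma and noise_sigma must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if set(self.subpop_channel_models) != set(self.channel_models):
            raise ValueError("subpopulation models must cover the same channels")


@dataclass
class GroundTruth:
    """True masks and per-cell table for one synthetic image.

    ``cell_table`` has one row per cell: centre, subpopulation flag and
    the true compartment mean of every channel, measured on the rendered
    noiseless image over the final masks (so the values are exact even
    where clumped cells contested pixels).
    """

    nuclear_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    cell_table: pd.DataFrame


class CellPlacementError(RuntimeError):
    """Raised when cells cannot be placed at the requested density."""


# ---------------------------------------------------------------------------
# image generation


def _ellipse_mask(shape, center, a, b, theta):
    """Boolean mask of an ellipse with semi-axes a, b rotated by theta."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_centres(spec: SyntheticImageSpec, radii: np.ndarray, rng) -> np.ndarray:
    """Sequential rejection placement of cell centres.

    ``radii`` are outer (cytoplasm) radii.  The first
    ``(1 - overlap_fraction) * n`` cells enforce centre distance
    >= r_i + r_j + 1 (fully disjoint); the remainder are attached to a
    random earlier cell at a distance that lets nuclei touch, producing
    clumps for the watershed to split.
    """
    n = spec.n_cells
    size = spec.image_size
    margin = radii + 2.0
    centres: list[tuple[float, float]] = []
    n_disjoint = n - int(round(spec.overlap_fraction * n))
    max_tries = 2000

    for i in range(n):
        placed = False
        for _ in range(max_tries):
            if i < n_disjoint or not centres:
                c = rng.uniform(margin[i], size - margin[i], size=2)
                ok = True
                for j, cj in enumerate(centres):
                    if np.hypot(c[0] - cj[0], c[1] - cj[1]) < radii[i] + radii[j] + 1:
                        ok = False
                        break
            else:
                j = int(rng.integers(0, len(centres)))
                ang = rng.uniform(0, 2 * np.pi)
                # close enough that cytoplasms merge and nuclei nearly touch
                d = 0.75 * (radii[i] + radii[j])
                c = np.array(centres[j]) + d * np.array([np.cos(ang), np.sin(ang)])
                ok = bool(
                    np.all(c >= margin[i]) and np.all(c <= size - margin[i])
                )
                # keep clumps at 2-3 cells: disallow a third neighbour closer
                # than the disjoint limit unless it is the anchor
                if ok:
                    close = sum(
                        1
                        for k, ck in enumerate(centres)
                        if np.hypot(c[0] - ck[0], c[1] - ck[1])
                        < radii[i] + radii[k] + 1
                    )
                    ok = close <= 2
            if ok:
                centres.append((float(c[0]), float(c[1])))
                placed = True
                break
        if not placed:
            raise CellPlacementError(
                f"could not place cell {i + 1}/{n} after {max_tries} tries; "
                f"reduce n_cells or image density"
            )
    return np.asarray(centres).reshape(n, 2)


def generate_image(
    spec: SyntheticImageSpec,
    *,
    image_id: str = "synth",
    patient_id: str = "",
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one multi-channel image plus its ground truth.

    Identical ``spec`` (including seed) reproduces bit-identical output.
    With ``n_cells == 0`` the image is pure background noise and both
    label maps are empty.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    shape = (size, size)
    n = spec.n_cells

    lo, hi = spec.nucleus_radius_range
    nuc_a = rng.uniform(lo, hi, size=n)
    ecc = rng.uniform(1.0 - spec.eccentricity_max, 1.0, size=n)
    nuc_b = nuc_a * ecc
    tlo, thi = spec.cytoplasm_thickness_range
    thick = rng.uniform(tlo, thi, size=n)
    theta = rng.uniform(0, np.pi, size=n)
    outer_a = nuc_a + thick
    outer_b = nuc_b + thick

    centres = (
        _place_centres(spec, np.maximum(outer_a, outer_b), rng)
        if n
        else np.zeros((0, 2))
    )
    is_sub = rng.random(n) < spec.subpop_fraction

    nuclear_mask = np.zeros(shape, dtype=np.int32)
    cyto_mask = np.zeros(shape, dtype=np.int32)
    for i in range(n):
        lab = i + 1
        outer = _ellipse_mask(shape, centres[i], outer_a[i], outer_b[i], theta[i])
        inner = _ellipse_mask(shape, centres[i], nuc_a[i], nuc_b[i], theta[i])
        # later cells overwrite contested pixels (deterministic order)
        cyto_mask[outer & ~inner] = lab
        cyto_mask[inner] = 0
        nuclear_mask[inner] = lab
        cyto_mask[nuclear_mask == lab] = 0

    # nuclei may have clipped earlier cells' cytoplasm; re-assert exclusivity
    cyto_mask[nuclear_mask > 0] = 0

    channels: dict[str, np.ndarray] = {}
    cell_values: dict[str, np.ndarray] = {}
    for name, base in spec.channel_models.items():
        sub = spec.subpop_channel_models[name]
        img = np.full(shape, float(spec.background))
        nuc_vals = np.empty(n)
        cyt_vals = np.empty(n)
        for i in range(n):
            m = sub if is_sub[i] else base
            nuc_vals[i] = max(m.min_intensity, rng.normal(m.nuclear_mean, m.cell_sd))
            cyt_vals[i] = max(m.min_intensity, rng.normal(m.cytoplasm_mean, m.cell_sd))
            img[nuclear_mask == i + 1] = nuc_vals[i]
            img[cyto_mask == i + 1] = cyt_vals[i]
        channels[name] = img
        cell_values[name] = np.stack([nuc_vals, cyt_vals])

    # exact per-cell means from the rendered noiseless image
    labels = np.arange(1, n + 1)
    rows: dict[str, np.ndarray | list] = {
        "cell_id": labels,
        "row": centres[:, 0] if n else np.array([]),
        "col": centres[:, 1] if n else np.array([]),
        "subpopulation": is_sub.astype(int),
    }
    for name, img in channels.items():
        for part, mask in (("nuclear", nuclear_mask), ("cytoplasm", cyto_mask)):
            mean = np.full(n, np.nan)
            if n:
                have = labels[np.isin(labels, np.unique(mask))]
                if have.size:
                    mean[have - 1] = ndimage.mean(img, mask, have)
            rows[f"{name}_{part}_mean"] = mean
    cell_table = pd.DataFrame(rows)

    noisy = {}
    for name, img in channels.items():
        out = img
        if spec.blur_sigma > 0:
            out = ndimage.gaussian_filter(out, spec.blur_sigma, mode="reflect")
        if spec.poisson_noise:
            out = rng.poisson(np.clip(out, 0, None)).astype(float)
        if spec.noise_sigma > 0:
            out = out + rng.normal(0.0, spec.noise_sigma, size=shape)
        noisy[name] = np.clip(out, 0.0, None)

    image = MultiChannelImage(
        channels=noisy,
        pixel_size=spec.pixel_size,
        image_id=image_id,
        patient_id=patient_id,
    )
    return image, GroundTruth(nuclear_mask, cyto_mask, cell_table)


def degrade_image(
    image: MultiChannelImage,
    blur_sigma: float,
    noise_sigma: float,
    *,
    seed: int = 0,
) -> MultiChannelImage:
    """Return a blurred and/or noised copy of ``image`` (input untouched).

    Emulates out-of-focus acquisition and low signal-to-noise for QC
    testing.  ``blur_sigma = noise_sigma = 0`` returns an identical copy.
    """
    if blur_sigma < 0 or noise_sigma < 0:
        raise ValueError("blur_sigma and noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = {}
    for name, arr in image.channels.items():
        a = arr.astype(float, copy=True)
        if blur_sigma > 0:
            a = ndimage.gaussian_filter(a, blur_sigma, mode="reflect")
        if noise_sigma > 0:
            a = np.clip(a + rng.normal(0.0, noise_sigma, size=a.shape), 0.0, None)
        out[name] = a
    return MultiChannelImage(
        channels=out,
        pixel_size=image.pixel_size,
        image_id=image.image_id,
        patient_id=image.patient_id,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic patient cohort.

    Each patient draws a prognostic subpopulation fraction f ~
    Beta(``subpop_beta``), receives 1-6 images rendered with that
    fraction, and a survival time from an exponential model with hazard
    ``baseline_hazard * exp(log_hazard_coef * f)`` (days^-1), censored by
    an independent exponential with rate ``censoring_rate``
    (``censoring_rate = 0`` means no censoring: every event observed).
    """

    n_patients: int = 20
    images_per_patient: tuple[int, int] = (1, 6)
    subpop_beta: tuple[float, float] = (2.0, 4.0)
    baseline_hazard: float = 1.0 / 1500.0
    log_hazard_coef: float = 1.5
    censoring_rate: float = 1.0 / 4000.0
    image_spec: SyntheticImageSpec = field(default_factory=SyntheticImageSpec)
    cohort_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.images_per_patient
        if not (1 <= lo <= hi <= 6):
            raise ValueError("images_per_patient must lie within 1..6")


@dataclass
class SyntheticCohort:
    """Images, ground truth, survival and manifest for one synthetic cohort."""

    images: dict[str, MultiChannelImage]
    ground_truth: dict[str, GroundTruth]
    survival: pd.DataFrame
    manifest: pd.DataFrame
    true_fractions: pd.Series

    @property
    def survival_records(self) -> list[SurvivalRecord]:
        return [
            SurvivalRecord(r.patient_id, r.time_days, int(r.event), r.cohort)
            for r in self.survival.itertuples()
        ]


def sample_survival(
    fractions: np.ndarray,
    *,
    baseline_hazard: float,
    log_hazard_coef: float,
    censoring_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival given covariate, independent exponential censoring.

    Returns (time, event).  With ``censoring_rate == 0`` every event is
    observed (censoring degenerate at +inf).
    """
    rate = baseline_hazard * np.exp(log_hazard_coef * fractions)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        t_cens = rng.exponential(1.0 / censoring_rate, size=fractions.size)
    else:
        t_cens = np.full(fractions.size, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # strictly positive times (exponential draws of 0.0 are measure-zero
    # but clip defensively for downstream validators)
    return np.maximum(time, 1e-6), event


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort: images, truth, survival, manifest."""
    rng = np.random.default_rng(spec.seed)
    fractions = rng.beta(*spec.subpop_beta, size=spec.n_patients)
    time, event = sample_survival(
        fractions,
        baseline_hazard=spec.baseline_hazard,
        log_hazard_coef=spec.log_hazard_coef,
        censoring_rate=spec.censoring_rate,
        rng=rng,
    )

    images: dict[str, MultiChannelImage] = {}
    truth: dict[str, GroundTruth] = {}
    manifest_rows = []
    lo, hi = spec.images_per_patient
    for p in range(spec.n_patients):
        pid = f"P{p + 1:03d}"
        n_img = int(rng.integers(lo, hi + 1))
        for k in range(n_img):
            iid = f"{pid}_img{k + 1}"
            ispec = replace(
                spec.image_spec,
                subpop_fraction=float(fractions[p]),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            img, gt = generate_image(ispec, image_id=iid, patient_id=pid)
            images[iid] = img
            truth[iid] = gt
            manifest_rows.append(
                {"image_id": iid, "patient_id": pid, "cohort": spec.cohort_label}
            )

    survival = pd.DataFrame(
        {
            "patient_id": [f"P{p + 1:03d}" for p in range(spec.n_patients)],
            "time_days": time,
            "event": event,
            "cohort": spec.cohort_label,
        }
    )
    return SyntheticCohort(
        images=images,
        ground_truth=truth,
        survival=survival,
        manifest=pd.DataFrame(manifest_rows),
        true_fractions=pd.Series(
            fractions, index=survival["patient_id"], name="subpop_fraction"
        ),
    )


def sample_ratio_cohort(
    n_patients: int,
    cells_per_patient: int,
    *,
    subpop_beta: tuple[float, float] = (2.0, 4.0),
    baseline_hazard: float = 1.0 / 1500.0,
    log_hazard_coef: float = 0.0,
    censoring_rate: float = 1.0 / 4000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Cell-level log2 N/C ratios plus survival, skipping image rendering.

    A fast path for the cut-point and forest simulations: each patient's
    cells are a two-component mixture — baseline cells (CD99 ratio
    centred at -2, Ki67 ratio at -1) and the planted subpopulation
    (CD99-low: ratio centred at +0.5; Ki67-positive: ratio at +1.5) —
    mirroring the intensity models of :func:`default_channel_models`.
    Returns (cells, survival, true_fractions); ``log_hazard_coef = 0``
    gives a survival-independent null cohort.
    """
    rng = np.random.default_rng(seed)
    fractions = rng.beta(*subpop_beta, size=n_patients)
    pids = [f"P{p + 1:03d}" for p in range(n_patients)]
    rows = []
    for p, pid in enumerate(pids):
        sub = rng.random(cells_per_patient) < fractions[p]
        cd99 = np.where(
            sub,
            rng.normal(0.5, 0.4, cells_per_patient),
            rng.normal(-2.0, 0.5, cells_per_patient),
        )
        ki67 = np.where(
            sub,
            rng.normal(1.5, 0.4, cells_per_patient),
            rng.normal(-1.0, 0.5, cells_per_patient),
        )
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "cd99_log2_nc_mean": cd99,
                    "ki67_log2_nc_mean": ki67,
                    "subpopulation": sub.astype(int),
                }
            )
        )
    cells = pd.concat(rows, ignore_index=True)
    time, event = sample_survival(
        fractions,
        baseline_hazard=baseline_hazard,
        log_hazard_coef=log_hazard_coef,
        censoring_rate=censoring_rate,
        rng=rng,
    )
    survival = pd.DataFrame(
        {"patient_id": pids, "time_days": time, "event": event, "cohort": "synthetic"}
    )
    return cells, survival, pd.Series(fractions, index=pids, name="subpop_fraction")


# ---------------------------------------------------------------------------
# disk I/O


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort to ``outdir``: multi-page TIFFs, label TIFFs, CSVs."""
    import tifffile

    out = Path(outdir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    paths = []
    for iid, img in cohort.images.items():
        path = out / "images" / f"{iid}.tif"
        stack = np.stack([img.channels[c] for c in img.channel_names]).astype(
            np.float32
        )
        tifffile.imwrite(
            path,
            stack,
            photometric="minisblack",
            metadata={"channel_names": img.channel_names, "pixel_size": img.pixel_size},
        )
        gt = cohort.ground_truth[iid]
        tifffile.imwrite(
            out / "truth" / f"{iid}_nuclear.tif", gt.nuclear_mask.astype(np.uint16)
        )
        tifffile.imwrite(
            out / "truth" / f"{iid}_cytoplasm.tif", gt.cytoplasm_mask.astype(np.uint16)
        )
        gt.cell_table.to_csv(out / "truth" / f"{iid}_cells.csv", index=False)
        paths.append(str(path))
    manifest = cohort.manifest.copy()
    manifest["image_path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
    cohort.survival.to_csv(out / "survival.csv", index=False)
    cohort.true_fractions.to_csv(out / "true_fractions.csv")
    return out


def read_image(path: str | Path) -> MultiChannelImage:
    """Read a multi-page TIFF written by :func:`write_cohort`."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = meta.get("channel_names") or [f"ch{i}" for i in range(stack.shape[0])]
    pixel_size = meta.get("pixel_size")
    return MultiChannelImage(
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        pixel_size=pixel_size,
        image_id=Path(path).stem,
    )


def write_image_spec(spec: SyntheticImageSpec, path: str | Path) -> None:
    d = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in spec.__dict__.items()
        if not isinstance(v, dict)
    }
    d["channel_models"] = {
        k: vars(v).copy() for k, v in spec.channel_models.items()
    }
    d["subpop_channel_models"] = {
        k: vars(v).copy() for k, v in spec.subpop_channel_models.items()
    }
    Path(path).write_text(json.dumps(d, indent=2))


def read_image_spec(path: str | Path) -> SyntheticImageSpec:
    d = json.loads(Path(path).read_text())
    for key in ("channel_models", "subpop_channel_models"):
        if key in d:
            d[key] = {k: ChannelModel(**v) for k, v in d[key].items()}
    for key in ("nucleus_radius_range", "cytoplasm_thickness_range", "images_per_patient"):
        if key in d:
            d[key] = tuple(d[key])
    return SyntheticImageSpec(**d)
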