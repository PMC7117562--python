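"""Synthetic Feulgen-stained slide simulator with densitometric ground truth.

Renders brightfield-like images of dark elliptical nuclei on a light
background.  Each nucleus carries a per-pixel decadic absorbance field — a
smooth radial dome, optionally modulated by chromatin-like texture — whose
discrete sum equals exactly the nucleus's true total absorbance

    A_true = absorbance_per_2N * dna_multiple,

so the Beer-Lambert transmitted intensity

    I = background_level * white * 10**(-a) (+ Gaussian noise, quantized)

makes the measured IOD proportional to DNA content by construction (the
pipeline's x10 OD scale gives IOD = 10 * A_true up to noise/quantization).
Lymphocyte controls are diploid (multiple ~ 1); the epithelial compartment
is a mixture of populations (e.g. 2N, a G2/4N shoulder, aneuploid clones).

Nuclei are placed without overlap by dart throwing, and every mask is also
exported as a pixel-edge polygon that rasterizes back to the identical
pixel set, so polygon-ROI and label-mask code paths agree exactly.  All
randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .roi_io import (
    CONTROL,
    EPITHELIAL,
    ImagePlane,
    NucleusROI,
    SampleEntry,
    StudyLayout,
    save_image,
    save_layout,
    save_rois,
)

__all__ = [
    "PopulationSpec",
    "SceneSpec",
    "NucleusTruth",
    "GroundTruth",
    "ConditionDesign",
    "StudyDesign",
    "DEFAULT_STUDY_DESIGN",
    "mask_to_polygon",
    "render_scene",
    "generate_cohort",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One epithelial subpopulation: its mixture weight and DNA content.

    ``ploidy_multiple`` is relative DNA content (1.0 = 2N, 2.0 = 4N);
    ``cv`` is the per-cell coefficient of variation of DNA content around
    that multiple (staining/measurement heterogeneity).
    """

    label: str
    fraction: float
    ploidy_multiple: float
    cv: float = 0.05
    count: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if not self.ploidy_multiple > 0:
            raise ValueError("ploidy_multiple must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one synthetic slide sample."""

    shape: tuple[int, int] = (512, 512)
    bit_depth: int = 16
    background_level: float = 1.0  # fraction of white transmitted off-tissue
    noise_sd: float = 0.01        # Gaussian intensity noise, fraction of white
    n_controls: int = 30
    n_epithelial: int = 160
    control_radius: tuple[float, float] = (4.0, 6.0)
    epithelial_radius: tuple[float, float] = (6.0, 9.0)
    absorbance_per_2N: float = 20.0  # total decadic absorbance of a 2N nucleus
    control_cv: float = 0.05
    texture_cv: float = 0.15      # chromatin-texture modulation inside nuclei
    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("2N", 0.92, 1.0, cv=0.05),
        PopulationSpec("4N", 0.08, 2.0, cv=0.05),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not 0 < self.background_level <= 1:
            raise ValueError("background_level must lie in (0, 1]")
        total = sum(p.fraction for p in self.populations)
        if self.populations and abs(total - 1.0) > 1e-9:
            raise ValueError(f"population fractions sum to {total}, not 1")

    @property
    def white(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass(frozen=True)
class NucleusTruth:
    roi_id: str
    cell_class: str
    population: str
    dna_multiple: float
    true_absorbance: float  # exact discrete integral of the absorbance field
    area_px: int


@dataclass(frozen=True)
class GroundTruth:
    nuclei: tuple[NucleusTruth, ...]
    masks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def by_id(self, roi_id: str) -> NucleusTruth:
        for n in self.nuclei:
            if n.roi_id == roi_id:
                return n
        raise KeyError(roi_id)


# ---------------------------------------------------------------------------
# Mask boundary tracing
# ---------------------------------------------------------------------------

def mask_to_polygon(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a connected pixel mask as an (x, y) polygon.

    Vertices lie on pixel corners (half-integer coordinates), so every mask
    pixel center is strictly inside the polygon and every outside center is
    strictly outside: rasterizing the polygon recovers the mask exactly.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    edges: dict[tuple[float, float], list[tuple[float, float]]] = {}

    def add(a: tuple[float, float], b: tuple[float, float]) -> None:
        edges.setdefault(a, []).append(b)

    in_mask = set(zip(rows.tolist(), cols.tolist()))
    for r, c in in_mask:
        # clockwise in (x right, y down) screen coordinates
        if (r - 1, c) not in in_mask:
            add((c - 0.5, r - 0.5), (c + 0.5, r - 0.5))
        if (r, c + 1) not in in_mask:
            add((c + 0.5, r - 0.5), (c + 0.5, r + 0.5))
        if (r + 1, c) not in in_mask:
            add((c + 0.5, r + 0.5), (c - 0.5, r + 0.5))
        if (r, c - 1) not in in_mask:
            add((c - 0.5, r + 0.5), (c - 0.5, r - 0.5))

    start = min(edges)
    path = [start]
    prev: tuple[float, float] | None = None
    cur = start
    while True:
        nxts = edges[cur]
        if len(nxts) == 1:
            nxt = nxts[0]
        else:
            # corner-touching configuration: prefer the sharpest right turn
            # to keep the outer boundary a single simple loop
            assert prev is not None
            dx, dy = cur[0] - prev[0], cur[1] - prev[1]
            nxt = max(nxts, key=lambda q: dx * (q[1] - cur[1]) - dy * (q[0] - cur[0]))
            edges[cur] = [q for q in nxts if q != nxt]
        prev, cur = cur, nxt
        if cur == start:
            break
        path.append(cur)

    poly = np.asarray(path, dtype=float)
    # merge collinear runs to shrink the vertex list
    keep = np.ones(len(poly), dtype=bool)
    for i in range(len(poly)):
        a, b, c = poly[i - 1], poly[i], poly[(i + 1) % len(poly)]
        u, v = b - a, c - b
        if u[0] * v[1] - u[1] * v[0] == 0:
            keep[i] = False
    return poly[keep]


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _place_ellipses(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radii: Sequence[tuple[float, float]],
    margin: float = 1.5,
    max_tries: int = 500,
) -> list[tuple[float, float, float, float]]:
    """Dart-throw non-overlapping ellipses; returns (cy, cx, ry, rx) tuples.

    Overlap is excluded conservatively via bounding circles plus a margin,
    which also guarantees the exported boundary polygons stay disjoint.
    """
    h, w = shape
    placed: list[tuple[float, float, float, float]] = []
    for rlo, rhi in radii:
        for attempt in range(max_tries):
            rx = rng.uniform(rlo, rhi)
            ry = rx * rng.uniform(0.85, 1.18)
            ry = min(max(ry, rlo), rhi)
            rmax = max(rx, ry)
            cy = rng.uniform(rmax + 1, h - rmax - 2)
            cx = rng.uniform(rmax + 1, w - rmax - 2)
            ok = True
            for py, px, pry, prx in placed:
                pr = max(prx, pry)
                if (cy - py) ** 2 + (cx - px) ** 2 < (rmax + pr + margin) ** 2:
                    ok = False
                    break
            if ok:
                placed.append((cy, cx, ry, rx))
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {len(placed) + 1}/{len(radii)} "
                f"after {max_tries} tries; image too crowded"
            )
    return placed


def _nucleus_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    geom: tuple[float, float, float, float],
    total_absorbance: float,
    texture_cv: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask and absorbance field for one nucleus.

    The field is a radial dome 1 - rho^2 (rho = elliptical radius), times
    optional positive texture noise, renormalized so its discrete sum is
    exactly ``total_absorbance``.
    """
    cy, cx, ry, rx = geom
    h, w = shape
    r0, r1 = max(int(np.floor(cy - ry)), 0), min(int(np.ceil(cy + ry)), h - 1)
    c0, c1 = max(int(np.floor(cx - rx)), 0), min(int(np.ceil(cx + rx)), w - 1)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    rho2 = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2
    inside = rho2 <= 1.0

    profile = np.where(inside, 1.0 - rho2, 0.0)
    if texture_cv > 0:
        tex = 1.0 + texture_cv * rng.standard_normal(profile.shape)
        profile = profile * np.clip(tex, 0.2, None)
    s = profile.sum()
    if s <= 0:
        raise RuntimeError("degenerate nucleus profile")
    profile *= total_absorbance / s

    mask = np.zeros(shape, dtype=bool)
    mask[rr[inside], cc[inside]] = True
    a_field = np.zeros(shape, dtype=float)
    a_field[rr[inside], cc[inside]] = profile[inside]
    return mask, a_field


def render_scene(
    spec: SceneSpec,
) -> tuple[ImagePlane, list[NucleusROI], GroundTruth]:
    """Render one synthetic slide: image, polygon ROIs and ground truth.

    Deterministic given the spec (including its seed): the same spec yields
    bit-identical images.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape

    # per-nucleus DNA multiples
    ctrl_mult = np.clip(
        rng.normal(1.0, spec.control_cv, spec.n_controls), 0.2, None
    )
    pops = list(spec.populations)
    counts = _population_counts(rng, pops, spec.n_epithelial)
    epi_mult: list[float] = []
    epi_pop: list[str] = []
    for p, k in zip(pops, counts):
        vals = np.clip(p.ploidy_multiple * rng.normal(1.0, p.cv, k), 0.1, None)
        epi_mult.extend(vals.tolist())
        epi_pop.extend([p.label] * k)
    order = rng.permutation(len(epi_mult))
    epi_mult = [epi_mult[i] for i in order]
    epi_pop = [epi_pop[i] for i in order]

    radii = [spec.control_radius] * spec.n_controls + [
        spec.epithelial_radius
    ] * spec.n_epithelial
    geoms = _place_ellipses(rng, spec.shape, radii)

    absorbance = np.zeros(spec.shape, dtype=float)
    rois: list[NucleusROI] = []
    truths: list[NucleusTruth] = []
    masks: dict[str, np.ndarray] = {}

    specs = [(CONTROL, f"C{i+1:03d}", float(m), "control-2N")
             for i, m in enumerate(ctrl_mult)]
    specs += [(EPITHELIAL, f"E{i+1:03d}", float(m), lab)
              for i, (m, lab) in enumerate(zip(epi_mult, epi_pop))]

    for geom, (cls, rid, mult, pop) in zip(geoms, specs):
        a_true = spec.absorbance_per_2N * mult
        mask, a_field = _nucleus_field(rng, spec.shape, geom, a_true, spec.texture_cv)
        absorbance += a_field
        poly = mask_to_polygon(mask)
        rois.append(NucleusROI(id=rid, cell_class=cls, polygon=poly))
        masks[rid] = mask
        truths.append(
            NucleusTruth(
                roi_id=rid, cell_class=cls, population=pop,
                dna_multiple=mult, true_absorbance=float(a_field.sum()),
                area_px=int(mask.sum()),
            )
        )

    white = spec.white
    intensity = spec.background_level * white * np.power(10.0, -absorbance)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd * white, spec.shape)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    pixels = np.clip(np.rint(intensity), 0, white).astype(dtype)
    plane = ImagePlane(pixels=pixels, bit_depth=spec.bit_depth, white_level=white)
    return plane, rois, GroundTruth(nuclei=tuple(truths), masks=masks)


def _population_counts(
    rng: np.random.Generator, pops: list[PopulationSpec], n_total: int
) -> list[int]:
    """Deterministic-leaning split of n_total cells across populations."""
    counts = [p.count for p in pops]
    fixed = sum(c for c in counts if c is not None)
    free = [i for i, c in enumerate(counts) if c is None]
    remaining = n_total - fixed
    if remaining < 0:
        raise ValueError("population count overrides exceed n_epithelial")
    if free:
        fracs = np.array([pops[i].fraction for i in free], dtype=float)
        fracs = fracs / fracs.sum()
        alloc = np.floor(fracs * remaining).astype(int)
        # distribute the rounding remainder by largest fractional part
        short = remaining - alloc.sum()
        frac_part = fracs * remaining - alloc
        for j in np.argsort(-frac_part)[:short]:
            alloc[j] += 1
        for i, k in zip(free, alloc):
            counts[i] = int(k)
    return [int(c) for c in counts]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionDesign:
    """Per-condition recipe: arm size and the per-sample peak-DI target law.

    Targets are drawn from a normal distribution truncated to
    ``target_range``; each sample's main epithelial population is centered
    at its target DI with per-cell spread ``cell_cv``, plus a small G2/4N
    shoulder at twice the target.
    """

    label: str
    n_samples: int
    target_mean: float
    target_sd: float
    target_range: tuple[float, float]
    cell_cv: float = 0.06
    g2_fraction: float = 0.08


@dataclass(frozen=True)
class StudyDesign:
    conditions: tuple[ConditionDesign, ...]
    scene: SceneSpec = SceneSpec()
    #: per-sample epithelial count range (inclusive); None pins the count to
    #: the scene's n_epithelial.  The default design uses the measurement
    #: protocol's 150-200 cells per sample.
    epithelial_range: tuple[int, int] | None = None


def _default_design() -> StudyDesign:
    """Five-arm colonic-lesion study: normal tissue, three polyp types and
    adenocarcinoma, with arm sizes 10/9/12/8/10 and per-sample peak-DI
    distributions matching the reported group means, SDs and ranges
    (widest spread in the adenocarcinoma arm)."""
    return StudyDesign(
        conditions=(
            ConditionDesign("NCT", 10, 0.95, 0.08, (0.81, 1.05), cell_cv=0.05),
            ConditionDesign("L-HP", 9, 1.08, 0.14, (0.81, 1.30), cell_cv=0.06),
            ConditionDesign("L-SA", 12, 1.11, 0.15, (0.95, 1.42), cell_cv=0.07),
            ConditionDesign("TA", 8, 1.22, 0.17, (1.02, 1.52), cell_cv=0.07),
            ConditionDesign("AC", 10, 1.46, 0.27, (1.20, 2.04), cell_cv=0.10),
        ),
        epithelial_range=(150, 200),
    )


DEFAULT_STUDY_DESIGN = _default_design()


def _draw_target(
    rng: np.random.Generator, cond: ConditionDesign
) -> float:
    lo, hi = cond.target_range
    if cond.target_sd <= 0:
        return float(np.clip(cond.target_mean, lo, hi))
    a = (lo - cond.target_mean) / cond.target_sd
    b = (hi - cond.target_mean) / cond.target_sd
    u = rng.uniform(0.0, 1.0)
    return float(
        stats.truncnorm.ppf(u, a, b, loc=cond.target_mean, scale=cond.target_sd)
    )


def generate_cohort(
    out_dir: str | Path,
    design: StudyDesign = DEFAULT_STUDY_DESIGN,
    seed: int = 0,
) -> StudyLayout:
    """Write a full synthetic study to disk: images, ROIs, layout and truth.

    Every sample gets a TIFF image and a polygon-ROI JSON; a layout CSV maps
    samples to conditions and a truth CSV records per-nucleus DNA multiples,
    exact absorbances and the per-sample intended peak DI.  Sub-seeds are
    derived deterministically from ``seed``, so the cohort is reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)

    entries: list[SampleEntry] = []
    truth_rows: list[dict] = []
    sample_rows: list[dict] = []
    for cond in design.conditions:
        for k in range(cond.n_samples):
            sub = int(root.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub)
            target = _draw_target(rng, cond)
            main_frac = 1.0 - cond.g2_fraction
            pops = (
                PopulationSpec("main", main_frac, target, cv=cond.cell_cv),
                PopulationSpec("G2", cond.g2_fraction, 2.0 * target, cv=cond.cell_cv),
            )
            if design.epithelial_range is not None:
                lo, hi = design.epithelial_range
                n_epi = int(rng.integers(lo, hi + 1))
            else:
                n_epi = design.scene.n_epithelial
            spec = replace(
                design.scene,
                populations=pops,
                n_epithelial=n_epi,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sid = f"{cond.label}-{k+1:02d}"
            plane, rois, truth = render_scene(spec)
            img_path = out / f"{sid}.tif"
            roi_path = out / f"{sid}.rois.json"
            save_image(img_path, plane)
            save_rois(roi_path, rois)
            entries.append(SampleEntry(sid, cond.label, str(img_path), str(roi_path)))
            sample_rows.append(
                {"sample_id": sid, "condition": cond.label, "target_peak_di": target}
            )
            for nt in truth.nuclei:
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "roi_id": nt.roi_id,
                        "cell_class": nt.cell_class,
                        "dna_multiple": nt.dna_multiple,
                        "true_A": nt.true_absorbance,
                    }
                )

    layout = StudyLayout(
        samples=tuple(entries),
        conditions=tuple(c.label for c in design.conditions),
    )
    save_layout(out / "layout.csv", layout)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    pd.DataFrame(sample_rows).to_csv(out / "targets.csv", index=False)
    (out / "design.json").write_text(
        json.dumps(
            {
                "seed": seed,
                "conditions": [
                    {
                        "label": c.label,
                        "n_samples": c.n_samples,
                        "target_mean": c.target_mean,
                        "target_sd": c.target_sd,
                        "target_range": list(c.target_range),
                    }
                    for c in design.conditions
                ],
            },
            indent=1,
        )
    )
    return layout
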