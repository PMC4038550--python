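"""End-to-end experiment drivers.

Two routes produce an :class:`~darkbench.quantify.IntensityDistribution` for
a scenario:

* :func:`population_condition` — the population-level shortcut: per-cell
  ground-truth totals straight from the generative model (no imaging).
* :func:`imaging_condition` — the full protocol: cells are placed in
  synthetic fields, rendered through the PSF + camera model, segmented from
  the brightfield image, background-subtracted and quantified from the
  fluorescence image; fields are generated until the requested number of
  cells has been pooled.

Per-field and per-component seeds are split deterministically from one master
seed with :class:`numpy.random.SeedSequence`, so runs are reproducible and
conditions are independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .benchmark import BenchmarkResult, compute_DS
from .imaging import CameraModel, FieldSpec, FieldImage, place_cells, render_field
from .quantify import (CellRecord, IntensityDistribution, estimate_background,
                       measure_cells, pool_condition)
from .scenarios import Scenario, simulate_population
from .segmentation import SegmentationParams, segment_brightfield

__all__ = [
    "population_condition",
    "imaging_condition",
    "benchmark_pair",
    "ImagingRunInfo",
]


@dataclass
class ImagingRunInfo:
    """Counts from one imaging-route condition (protocol audit trail)."""

    n_fields: int = 0
    n_placed: int = 0
    n_segmented: int = 0
    n_pooled: int = 0
    saturation_fraction: float = 0.0
    fields: list[FieldImage] = field(default_factory=list)


def population_condition(scenario: Scenario, n: int, seed: int,
                         condition: str | None = None,
                         replicate_id: str = "r0") -> IntensityDistribution:
    """Ground-truth per-cell totals pooled into an intensity distribution."""
    pop = simulate_population(scenario, n, seed, replicate_id=replicate_id)
    return IntensityDistribution(condition=condition or scenario.name,
                                 values=pop.total_values,
                                 replicate_ids=(replicate_id,))


def imaging_condition(scenario: Scenario, n_cells: int, seed: int,
                      spec: FieldSpec | None = None,
                      camera: CameraModel | None = None,
                      seg_params: SegmentationParams | None = None,
                      condition: str | None = None,
                      replicate_id: str = "r0",
                      max_fields: int = 200,
                      keep_fields: bool = False,
                      bg_dilation_px: int = 5,
                      ) -> tuple[IntensityDistribution, ImagingRunInfo]:
    """Full imaging route: simulate, render, segment and quantify ``n_cells``.

    Fields of ``spec.n_cells_target`` cells are generated until ``n_cells``
    have been pooled (or ``max_fields`` reached, with a warning).  The pooled
    corrected means come from the *segmented* masks, as in a real experiment;
    ground truth is retained per field only when ``keep_fields`` is set.
    """
    spec = spec or FieldSpec()
    camera = camera or CameraModel()
    seg_params = seg_params or SegmentationParams()
    condition = condition or scenario.name
    ss = np.random.SeedSequence(seed)

    records: list[CellRecord] = []
    info = ImagingRunInfo()
    sat = []
    while info.n_pooled < n_cells and info.n_fields < max_fields:
        fseed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        geoms = place_cells(spec, spec.n_cells_target, seed=fseed)
        pop = simulate_population(scenario, len(geoms), seed=fseed + 1,
                                  replicate_id=replicate_id)
        img = render_field(pop.total_values, geoms, spec, camera, seed=fseed + 2)
        mask = segment_brightfield(img.brightfield, seg_params)
        bg = estimate_background(img.fluorescence, mask, dilation_px=bg_dilation_px)
        recs = measure_cells(mask, img.fluorescence, bg, camera.gain,
                             field_id=f"f{info.n_fields}",
                             replicate_id=replicate_id, condition=condition)
        records.extend(recs)
        info.n_fields += 1
        info.n_placed += len(geoms)
        info.n_segmented += mask.n_cells
        info.n_pooled += len(recs)
        sat.append(img.saturation_fraction)
        if keep_fields:
            info.fields.append(img)
    if info.n_pooled < n_cells:
        warnings.warn(
            f"pooled only {info.n_pooled} of {n_cells} requested cells "
            f"after {info.n_fields} fields", stacklevel=2)
    info.saturation_fraction = float(np.mean(sat)) if sat else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        dist = pool_condition(records, condition, min_cells=1)
    # trim to the requested count so conditions are size-matched
    if dist.n > n_cells:
        dist = IntensityDistribution(condition=condition,
                                     values=dist.values[:n_cells],
                                     replicate_ids=dist.replicate_ids)
        info.n_pooled = n_cells
    return dist, info


def benchmark_pair(ev: IntensityDistribution, af: IntensityDistribution,
                   n_boot: int = 2000, seed: int = 0) -> BenchmarkResult:
    """Convenience alias of :func:`darkbench.benchmark.compute_DS`."""
    return compute_DS(ev, af, n_boot=n_boot, seed=seed)
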