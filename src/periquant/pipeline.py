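"""End-to-end orchestration: phantom → segmentation → geometry → metrics → stats.

A run is driven by a :class:`RunConfig` that either points at image files
(with their mandatory calibration) or describes a phantom cohort:
``n_units`` animals × a set of surface conditions, each condition shifting
the planted bone-contact fraction and immediate-layer fill.  Every section
gets its own child seed spawned deterministically from the run seed, so a
rerun with the same configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, geometry, io, metrics, phantom, segmentation, stats

logger = logging.getLogger("periquant")


@dataclass
class ConditionSpec:
    """One surface condition's planted effects (phantom cohorts)."""

    name: str
    contact_shift: float = 0.0
    layer1_shift: float = 0.0


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_units: int = 6
    n_sections: int = 3
    conditions: list[ConditionSpec] = field(default_factory=lambda: [
        ConditionSpec("control"),
        ConditionSpec("coated", contact_shift=0.2, layer1_shift=0.15),
    ])
    phantom_spec: phantom.PhantomSpec = field(
        default_factory=phantom.PhantomSpec
    )
    seg_params: segmentation.SegmentationParams = field(
        default_factory=segmentation.SegmentationParams
    )
    #: per-image parameter overrides, keyed by section id
    seg_overrides: dict = field(default_factory=dict)
    #: measurement noise on the cohort baselines
    unit_noise_sd: float = 0.02
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = io.load_yaml(path)
        kwargs = {}
        for key in ("seed", "n_units", "n_sections", "unit_noise_sd",
                    "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "conditions" in raw:
            kwargs["conditions"] = [
                ConditionSpec(**c) for c in raw["conditions"]
            ]
        if "phantom_spec" in raw:
            ps = dict(raw["phantom_spec"])
            if "bone_fraction_per_layer" in ps:
                ps["bone_fraction_per_layer"] = tuple(
                    ps["bone_fraction_per_layer"]
                )
            if "color_model" in ps:
                ps["color_model"] = phantom.ColorModel(**ps["color_model"])
            kwargs["phantom_spec"] = phantom.PhantomSpec(**ps)
        if "seg_params" in raw:
            kwargs["seg_params"] = segmentation.SegmentationParams(
                **raw["seg_params"]
            )
        if "seg_overrides" in raw:
            kwargs["seg_overrides"] = dict(raw["seg_overrides"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _child_seed(root: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=root, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _clip01(x: float) -> float:
    return float(min(max(x, 0.0), 1.0))


def measure_section(
    image,
    seg_params: segmentation.SegmentationParams,
    defect_width_mm: float,
    section_id: str = "",
) -> metrics.SectionMetrics:
    """Segment one histology image and compute its metric record."""
    implant = segmentation.segment_implant(image, seg_params)
    bone = segmentation.segment_bone(image, seg_params, implant_mask=implant)
    masks = geometry.build_mask_set(
        implant, bone, image.pixel_area, defect_width_mm
    )
    return metrics.section_metrics(masks, image.pixel_area, section_id)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute a phantom-backed cohort run and write the result bundle.

    Writes ``sections.csv`` (one row per cross-section), ``discs.csv``
    (per condition × unit means), ``pvalues_<metric>.csv`` pairwise
    Wilcoxon matrices, ``friedman.csv`` and ``manifest.json``.  Returns the
    bundle as a dict of DataFrames.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = config.phantom_spec
    section_rows = []
    disc_rows = []
    failed_sections = 0
    for ci, cond in enumerate(config.conditions):
        for ui in range(config.n_units):
            unit_rng = np.random.default_rng(
                _child_seed(config.seed, ci, ui)
            )
            unit_contact = _clip01(
                base.contact_fraction + cond.contact_shift
                + unit_rng.normal(0.0, config.unit_noise_sd)
            )
            layers = list(base.bone_fraction_per_layer)
            layers[0] = _clip01(
                layers[0] + cond.layer1_shift
                + unit_rng.normal(0.0, config.unit_noise_sd)
            )
            disc_sections = []
            for si in range(config.n_sections):
                section_id = f"{cond.name}/unit{ui}/sec{si}"
                spec = dataclasses.replace(
                    base,
                    contact_fraction=unit_contact,
                    bone_fraction_per_layer=tuple(layers),
                    seed=_child_seed(config.seed, ci, ui, si),
                )
                image, _ = phantom.generate_histology_phantom(spec)
                params = config.seg_params
                if section_id in config.seg_overrides:
                    params = params.override(
                        **config.seg_overrides[section_id]
                    )
                try:
                    sm = measure_section(
                        image, params, base.defect_width_mm, section_id
                    )
                except (segmentation.DetectionError,
                        metrics.MetricError) as exc:
                    logger.error("section %s unusable: %s", section_id, exc)
                    failed_sections += 1
                    continue
                disc_sections.append(sm)
                section_rows.append({
                    "section_id": sm.section_id,
                    "condition": cond.name,
                    "unit": ui,
                    "bone_area_mm2": sm.bone_area_mm2,
                    "bone_density_pct": sm.bone_density_pct,
                    "bic_pct": sm.bic_pct,
                    "layer_immediate_mm2": sm.layer_areas_mm2[0],
                    "layer_intermediate_mm2": sm.layer_areas_mm2[1],
                    "layer_remote_mm2": sm.layer_areas_mm2[2],
                })
            if not disc_sections:
                logger.error(
                    "disc %s/unit%d has no usable sections; excluded from "
                    "stats", cond.name, ui,
                )
                continue
            summary = metrics.aggregate_disc(disc_sections)
            row = {"condition": cond.name, "unit": ui,
                   "n_sections": summary.n_sections}
            for key, val in summary.mean.items():
                row[f"{key}_mean"] = val
                row[f"{key}_sd"] = summary.sd[key]
            disc_rows.append(row)

    sections_df = pd.DataFrame(section_rows)
    discs_df = pd.DataFrame(disc_rows)
    io.write_section_table(out_dir / "sections.csv", sections_df)
    discs_df.to_csv(out_dir / "discs.csv", index=False, float_format="%.6g")

    bundle: dict = {"sections": sections_df, "discs": discs_df}
    stat_tables = {}
    for metric_name in ("bic_pct", "bone_area_mm2", "bone_density_pct"):
        wide = discs_df.pivot(
            index="unit", columns="condition", values=f"{metric_name}_mean"
        )[[c.name for c in config.conditions]].dropna()
        if wide.shape[0] >= 2 and wide.shape[1] >= 2:
            pmat = stats.pairwise_wilcoxon_matrix(wide)
            pmat.to_csv(out_dir / f"pvalues_{metric_name}.csv",
                        float_format="%.3f")
            fr = stats.friedman(wide.to_numpy())
            stat_tables[metric_name] = {
                "pairwise": pmat,
                "friedman_chi2": fr.statistic,
                "friedman_p": fr.p_two_sided,
            }
    if stat_tables:
        pd.DataFrame(
            {
                m: {"chi2": t["friedman_chi2"], "p": t["friedman_p"]}
                for m, t in stat_tables.items()
            }
        ).T.to_csv(out_dir / "friedman.csv", float_format="%.4f")
    bundle["stats"] = stat_tables

    manifest = {
        "seed": config.seed,
        "config_hash": io.config_hash(config.to_dict()),
        "periquant_version": __version__,
        "n_sections_written": len(section_rows),
        "n_sections_failed": failed_sections,
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
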