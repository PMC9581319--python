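"""Tables, images, run configuration and the end-to-end pipeline.

CSV dialect is fixed: comma-separated, UTF-8, mandatory header, ``.``
decimal; floats are written with 9 significant digits.  Images are
grayscale TIFF (PNG accepted); label maps round-trip losslessly as
16-bit TIFF.  Every pipeline output directory carries a provenance
record (config hash, seed, per-stage row counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import graft_scoring, hydraulics, morphometry, stats, synthetic_data
from .errors import SchemaError, XylograftError
from .growth import LogisticParams, fit_logistic, summarize_growth

__all__ = [
    "read_table",
    "write_table",
    "read_image",
    "write_image",
    "RunConfig",
    "run_pipeline",
    "PipelineError",
]

logger = logging.getLogger("xylograft")

VESSEL_TABLE_COLUMNS = [
    "vessel_id", "x_px", "y_px", "area_um2", "diameter_um", "sector", "xy_id",
]


class PipelineError(XylograftError, RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def read_table(path, required_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, checking the header against ``required_columns``."""
    df = pd.read_csv(path)
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing column(s) {missing}; expected {required_columns}"
            )
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def write_image(image: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)
    return path


def vessel_table(records) -> pd.DataFrame:
    """Vessel records as the canonical CSV shape."""
    return pd.DataFrame(
        [
            {
                "vessel_id": r.vessel_id,
                "x_px": r.centroid_rc[1],
                "y_px": r.centroid_rc[0],
                "area_um2": r.lumen_area_um2,
                "diameter_um": r.diameter_um,
                "sector": r.sector,
                "xy_id": r.xy_id,
            }
            for r in records
        ],
        columns=VESSEL_TABLE_COLUMNS,
    )


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class RunConfig:
    """Configuration of the demo pipeline: a simulated 3x3 factorial study.

    Factor A levels play the role of cultivars (each tied to a vessel
    preset), factor B of grafting techniques; the per-cell growth
    carrying capacities and necrosis fractions are mild perturbations of
    the base values so every stage has signal to find.
    """

    seed: int = 0
    out_dir: str = "xylograft_run"
    levels_a: tuple[str, ...] = ("glera_like", "teroldego_like", "cabernet_like")
    levels_b: tuple[str, ...] = ("Omega", "WT", "FC")
    n_sections: int = 5
    section_px: int = 512
    pith_radius_um: float = 60.0
    phloem_width_um: float = 40.0
    noise_sigma: float = 10.0
    n_plants: int = 15
    growth_k_base: float = 90.0
    growth_k_cv: float = 0.25  # between-plant biological variability of K
    growth_r: float = 0.12
    growth_noise_sigma: float = 2.0
    n_union_images: int = 3
    union_px: int = 256
    necrosis_base_fraction: float = 0.3
    necrosis_rep_sd: float = 0.03  # between-replicate SD of the true fraction
    alpha: float = 0.05
    ranking_policy: tuple[str, ...] = graft_scoring.DEFAULT_POLICY
    poiseuille_coefficient: float = 1.28

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise SchemaError(f"unknown config key(s): {sorted(bad)}")
        for key in ("levels_a", "levels_b", "ranking_policy"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(base_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# pipeline stages

def _traits_stage(cfg: RunConfig) -> tuple[pd.DataFrame, dict[str, stats.AnovaTable]]:
    rows = []
    for ia, la in enumerate(cfg.levels_a):
        pop_base = synthetic_data.SECTION_PRESETS.get(
            la, synthetic_data.SECTION_PRESETS["glera_like"]
        )
        for ib, lb in enumerate(cfg.levels_b):
            for rep in range(cfg.n_sections):
                seed = _stage_seed(cfg.seed, f"traits:{ia}:{ib}:{rep}")
                spec = synthetic_data.SectionImageSpec(
                    width_px=cfg.section_px,
                    height_px=cfg.section_px,
                    pith_radius_um=cfg.pith_radius_um,
                    phloem_width_um=cfg.phloem_width_um,
                    vessels=dataclasses.replace(pop_base, seed=seed),
                    noise_sigma=cfg.noise_sigma,
                    seed=seed,
                )
                gt = synthetic_data.render_xylem_section(spec)
                recs = morphometry.segment_vessel_lumens(gt.image, spec.pixel_size_um)
                recs = morphometry.assign_sectors(
                    recs, gt.xy_label_map, gt.sector_of_label
                )
                regions = morphometry.regions_from_label_map(
                    gt.xy_label_map, gt.sector_of_label, spec.pixel_size_um, recs
                )
                constants = hydraulics.HydraulicConstants(
                    coefficient=cfg.poiseuille_coefficient
                )
                prof = hydraulics.profile_section(recs, regions, constants)["section"]
                rows.append(
                    {
                        "factorA": la, "factorB": lb, "replicate": rep + 1,
                        "vd": prof.vd, "vaf": prof.vaf_percent,
                        "dh": prof.dh_um, "kst": prof.kst,
                        "n_vessels": prof.n_vessels,
                    }
                )
    table = pd.DataFrame(rows)
    anovas = {}
    for trait in ("vd", "vaf", "dh", "kst"):
        sub = table.rename(columns={trait: "value"})[["factorA", "factorB", "value"]]
        anovas[trait] = stats.two_way_anova(sub)
    return table, anovas


def _growth_stage(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, stats.AnovaTable]:
    fit_rows = []
    for ia, la in enumerate(cfg.levels_a):
        for ib, lb in enumerate(cfg.levels_b):
            # mild cell effects on the carrying capacity, plus
            # between-plant biological variability of K
            k_cell = cfg.growth_k_base * (1.0 + 0.12 * ia - 0.06 * ib)
            cell_seed = _stage_seed(cfg.seed, f"growth:{ia}:{ib}")
            rng = np.random.default_rng(cell_seed)
            for plant in range(cfg.n_plants):
                k_plant = max(
                    5.0, k_cell * (1.0 + cfg.growth_k_cv * rng.standard_normal())
                )
                spec = synthetic_data.GrowthSimSpec(
                    true_params=LogisticParams(k=k_plant, y0=1.0, r=cfg.growth_r),
                    noise_sigma=cfg.growth_noise_sigma,
                    n_replicates=1,
                    seed=int(rng.integers(2**31)),
                )
                series = synthetic_data.simulate_growth_series(spec)[0]
                fit = fit_logistic(series)
                fit_rows.append(
                    {
                        "factorA": la, "factorB": lb, "plant_id": series.plant_id,
                        "k": fit.k, "y0": fit.y0, "r": fit.r,
                        "r_squared": fit.r_squared,
                    }
                )
    fits = pd.DataFrame(fit_rows)
    summary = summarize_growth(fits)
    k_table = fits.rename(columns={"k": "value"})[["factorA", "factorB", "value"]]
    return fits, summary, stats.two_way_anova(k_table)


def _necrosis_stage(cfg: RunConfig) -> tuple[pd.DataFrame, stats.AnovaTable]:
    rows = []
    for ia, la in enumerate(cfg.levels_a):
        for ib, lb in enumerate(cfg.levels_b):
            frac_cell = min(
                0.95, cfg.necrosis_base_fraction * (1.0 + 0.25 * ib + 0.1 * ia)
            )
            cell_rng = np.random.default_rng(
                _stage_seed(cfg.seed, f"necrosis:{ia}:{ib}")
            )
            for rep in range(cfg.n_union_images):
                frac_true = float(
                    np.clip(
                        frac_cell + cfg.necrosis_rep_sd * cell_rng.standard_normal(),
                        0.01, 0.99,
                    )
                )
                spec = synthetic_data.GraftUnionImageSpec(
                    width_px=cfg.union_px, height_px=cfg.union_px,
                    necrotic_fraction_true=frac_true,
                    seed=int(cell_rng.integers(2**31)),
                )
                image, _, roi = synthetic_data.render_graft_union_image(spec)
                meas = morphometry.measure_necrosis_fraction(image, roi)
                rows.append(
                    {
                        "factorA": la, "factorB": lb, "replicate": rep + 1,
                        "percent_necrosis": meas.percent_necrosis,
                        "true_fraction": frac_true,
                    }
                )
    table = pd.DataFrame(rows)
    transformed = table.assign(
        value=stats.arcsine_sqrt_transform(table["percent_necrosis"] / 100.0)
    )[["factorA", "factorB", "value"]]
    return table, stats.two_way_anova(transformed)


def _scoring_stage(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    frames = []
    for trial in (1, 2):
        t = graft_scoring.load_printed_evaluations(trial)
        conc = graft_scoring.ranking_concordance(t, cfg.ranking_policy)
        t = t.assign(trial=trial)
        frames.append((t, conc))
    merged = pd.concat([f for f, _ in frames], ignore_index=True)
    total = sum(c["n"] for _, c in frames)
    matches = sum(c["matches"] for _, c in frames)
    summary = {
        "policy": list(cfg.ranking_policy),
        "n": total,
        "matches": matches,
        "concordance": matches / total,
        "deviations": [d for _, c in frames for d in c["deviations"]],
    }
    return merged, summary


def run_pipeline(config: RunConfig) -> dict:
    """Run generator -> morphometry -> hydraulics/growth/scoring -> stats
    and write the report bundle under ``config.out_dir``.

    Returns a dict of the in-memory results.  Any stage failure raises
    :class:`PipelineError` naming the stage; outputs written before the
    failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def _run(stage: str, fn):
        logger.info("stage %s: start", stage)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            _write_provenance(out, provenance)
            raise PipelineError(stage, exc) from exc

    traits, trait_anovas = _run("traits", lambda: _traits_stage(config))
    write_table(traits, out / "trait_replicates.csv")
    anova_rows = []
    for trait, at in trait_anovas.items():
        t = at.table.reset_index(names="effect").assign(trait=trait)
        anova_rows.append(t)
    write_table(pd.concat(anova_rows, ignore_index=True), out / "trait_anova.csv")
    provenance["stages"]["traits"] = {"rows": len(traits)}
    results["traits"] = traits
    results["trait_anovas"] = trait_anovas

    fits, growth_summary, k_anova = _run("growth", lambda: _growth_stage(config))
    write_table(fits, out / "growth_fits.csv")
    write_table(growth_summary, out / "growth_summary.csv")
    write_table(
        k_anova.table.reset_index(names="effect"), out / "growth_k_anova.csv"
    )
    provenance["stages"]["growth"] = {"rows": len(fits)}
    results["growth_fits"] = fits
    results["growth_summary"] = growth_summary
    results["growth_k_anova"] = k_anova

    necrosis, necrosis_anova = _run("necrosis", lambda: _necrosis_stage(config))
    write_table(necrosis, out / "necrosis_measurements.csv")
    write_table(
        necrosis_anova.table.reset_index(names="effect"), out / "necrosis_anova.csv"
    )
    provenance["stages"]["necrosis"] = {"rows": len(necrosis)}
    results["necrosis"] = necrosis
    results["necrosis_anova"] = necrosis_anova

    scores, concordance = _run("scoring", lambda: _scoring_stage(config))
    write_table(scores, out / "graft_scores.csv")
    (out / "ranking_concordance.json").write_text(json.dumps(concordance, indent=2))
    provenance["stages"]["scoring"] = {
        "rows": len(scores), "concordance": concordance["concordance"],
    }
    results["scores"] = scores
    results["concordance"] = concordance

    _write_provenance(out, provenance)
    results["provenance"] = provenance
    return results


def _write_provenance(out: Path, provenance: dict) -> None:
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=list)
    )
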