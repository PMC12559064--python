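"""Per-patient orchestration and cohort batching.

One patient = one CT volume + lung/vein masks.  The pipeline runs the
attenuation, heterogeneity and centralization analyses in order and emits
a JSON record with the six headline metrics (three compartment
proportions, two entropies, one slope), QC flags, and full provenance
(config hash, seed, software version).  Stages after classification are
independent: a late-stage failure is recorded without discarding earlier
metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attenuation import (classify_voxels, compartment_proportions,
                          fit_three_component_model, DEFAULT_SUBSAMPLE_CAP)
from .centralization import centralization_metric
from .heterogeneity import heterogeneity_metrics
from .imaging import (CTVolume, QCWarning, SegmentationSet, extract_lung_samples,
                      read_ct_volume, read_segmentation, write_labels,
                      DEFAULT_CLIP_RANGE)

__all__ = ["RunConfig", "PatientMetrics", "analyze_arrays", "analyze_patient",
           "analyze_cohort"]

log = logging.getLogger("perfmosaic")


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a pipeline run; serialized into every report."""

    clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE
    bins: int = 32
    n_regions: int = 21
    max_iter: int = 500
    tol: float = 1e-4
    weight_concentration_prior: float = 1.0 / 3.0
    subsample_cap: int = DEFAULT_SUBSAMPLE_CAP
    seed: int = 0
    label_map: dict = field(
        default_factory=lambda: {"lung_left": 1, "lung_right": 2, "veins": 3})
    column_map: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clip_range"] = list(d["clip_range"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "clip_range" in data:
            data["clip_range"] = tuple(data["clip_range"])
        return cls(**data)


@dataclass
class PatientMetrics:
    """Per-patient result record; the six headline scalars plus provenance."""

    patient_id: str
    proportions_weight: dict
    proportions_count: dict
    entropy: dict
    centralization: dict
    model: dict
    qc_flags: list
    errors: dict
    config_hash: str
    seed: int
    version: str

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def headline(self) -> dict[str, float]:
        """The six headline metrics in a flat mapping (NaN where failed)."""
        out = {
            "prop_oligemic": self.proportions_weight.get("oligemic", np.nan),
            "prop_normal": self.proportions_weight.get("normal", np.nan),
            "prop_hyperemic": self.proportions_weight.get("hyperemic", np.nan),
            "entropy_high": self.entropy.get("entropy_high_mean", np.nan),
            "entropy_medium": self.entropy.get("entropy_medium_mean", np.nan),
            "slope_mean": self.centralization.get("slope_mean", np.nan),
        }
        return out


def analyze_arrays(volume: CTVolume, seg: SegmentationSet,
                   config: RunConfig = RunConfig(),
                   patient_id: str = "patient") -> PatientMetrics:
    """Run the full per-patient analysis on in-memory objects.

    Attenuation (mixture fit + voxel classification + proportions) runs
    first; heterogeneity and centralization follow independently, and a
    hard error in one of them is recorded under ``errors`` without
    discarding the rest.
    """
    qc: list[str] = []
    errors: dict[str, str] = {}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", QCWarning)
        t0 = time.perf_counter()
        left = extract_lung_samples(volume, seg, "left", config.clip_range)
        right = extract_lung_samples(volume, seg, "right", config.clip_range)
        pooled = np.concatenate([left.values, right.values])
        model = fit_three_component_model(
            pooled, max_iter=config.max_iter, tol=config.tol,
            weight_concentration_prior=config.weight_concentration_prior,
            subsample_cap=config.subsample_cap, seed=config.seed)
        mask = classify_voxels(volume, seg, model, config.clip_range)
        by_weight, by_count = compartment_proportions(model, mask)
        log.info("attenuation stage done in %.2fs", time.perf_counter() - t0)

        t0 = time.perf_counter()
        het = heterogeneity_metrics(mask, seg, volume.spacing, bins=config.bins)
        qc.extend(het.flags)
        log.info("heterogeneity stage done in %.2fs", time.perf_counter() - t0)

        cent_dict: dict = {}
        try:
            t0 = time.perf_counter()
            cent = centralization_metric(volume, seg,
                                         clip_range=config.clip_range,
                                         n_regions=config.n_regions)
            cent_dict = cent.as_dict()
            log.info("centralization stage done in %.2fs", time.perf_counter() - t0)
        except (ValueError, RuntimeError) as exc:
            errors["centralization"] = str(exc)
            log.warning("centralization stage failed: %s", exc)
        qc.extend(str(w.message) for w in caught
                  if issubclass(w.category, QCWarning))

    model_dict = {
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "sds": model.sds.tolist(),
        "converged": model.fit_info.get("converged"),
        "n_iterations": model.fit_info.get("n_iterations"),
        "n_samples_used": model.fit_info.get("n_samples_used"),
    }
    return PatientMetrics(
        patient_id=str(patient_id),
        proportions_weight=by_weight.as_dict(),
        proportions_count=by_count.as_dict(),
        entropy=het.as_dict(),
        centralization=cent_dict,
        model=model_dict,
        qc_flags=qc,
        errors=errors,
        config_hash=config.config_hash,
        seed=config.seed,
        version=__version__,
    )


def analyze_patient(ct_path, seg_paths, config: RunConfig = RunConfig(),
                    patient_id: str | None = None, out_dir=None,
                    export_mask: bool = False) -> PatientMetrics:
    """Analyze one patient from files; optionally write the JSON report.

    ``seg_paths`` is either a single multi-label NIfTI path (interpreted
    with ``config.label_map``) or a mapping of per-structure mask paths.
    """
    volume = read_ct_volume(ct_path)
    label_map = config.label_map if isinstance(seg_paths, (str, Path)) else None
    seg = read_segmentation(seg_paths, volume, label_map=label_map)
    if patient_id is None:
        patient_id = Path(ct_path).stem.replace(".nii", "")
    result = analyze_arrays(volume, seg, config, patient_id=patient_id)
    result.qc_flags[:0] = volume.qc_flags()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        record = result.as_dict()
        record["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / f"{patient_id}.json").write_text(
            json.dumps(record, indent=2, sort_keys=True))
        if export_mask:
            from .attenuation import AttenuationModel, GaussianComponent
            comps = tuple(GaussianComponent(w, m, s) for w, m, s in zip(
                result.model["weights"], result.model["means"],
                result.model["sds"]))
            mask = classify_voxels(volume, seg,
                                   AttenuationModel(components=comps),
                                   config.clip_range)
            write_labels(mask.labels, volume.spacing,
                         out / f"{patient_id}_compartments.nii.gz")
    return result


def analyze_cohort(manifest, config: RunConfig = RunConfig(),
                   out_csv=None) -> pd.DataFrame:
    """Batch per-patient analysis over a manifest.

    The manifest (CSV path or DataFrame) needs columns ``patient_id``,
    ``ct`` and ``seg``; failures are recorded per row in an ``error``
    column without aborting the batch.
    """
    if not isinstance(manifest, pd.DataFrame):
        try:
            manifest = pd.read_csv(manifest)
        except (OSError, pd.errors.ParserError) as exc:
            raise ValueError(f"unreadable manifest: {exc}") from exc
    for col in ("patient_id", "ct", "seg"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing column {col!r}")
    rows = []
    for rec in manifest.itertuples(index=False):
        row: dict = {"patient_id": rec.patient_id, "error": ""}
        try:
            result = analyze_patient(rec.ct, rec.seg, config,
                                     patient_id=str(rec.patient_id))
            row.update(result.headline())
            row.update({f"prop_{k}_count": v
                        for k, v in result.proportions_count.items()})
            row.update({k: v for k, v in result.entropy.items()
                        if k.endswith(("left", "right"))})
            row.update({k: v for k, v in result.centralization.items()
                        if k != "slope_mean"})
            row["qc_flags"] = "; ".join(result.qc_flags)
            row["stage_errors"] = "; ".join(
                f"{k}: {v}" for k, v in result.errors.items())
            row["config_hash"] = result.config_hash
            row["seed"] = result.seed
            row["version"] = result.version
        except Exception as exc:  # per-row isolation is the contract
            row["error"] = f"{type(exc).__name__}: {exc}"
            log.error("patient %s failed: %s", rec.patient_id, exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
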