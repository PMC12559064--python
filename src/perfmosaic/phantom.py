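"""Synthetic CTPA-like chest phantoms with known ground truth.

No public CTPA dataset with lung/vein segmentations accompanies this
package, so every pipeline stage is exercised on generated phantoms whose
ground truth is known exactly:

* a soft-tissue body ellipsoid in air,
* two ellipsoidal lungs whose voxels are drawn from a three-component
  Gaussian attenuation mixture (oligemic / normal / hyperemic),
* spatially coherent compartment patches, produced by thresholding a
  seeded smooth random field at quantiles matching the target weights
  (patch size controlled by ``blob_scale``),
* an optional linear hilum-to-pleura attenuation gradient, added as a
  deterministic function of the true relative distance,
* contrast-filled vein capsules running from each lung's medial surface
  toward the mediastinum, whose extrapulmonary centroid (the true hilar
  point) is recorded.

Everything is reproducible from the spec's seed.  The module also builds
a synthetic per-patient clinical table with prescribed Spearman rank
correlations via a Gaussian copula, for testing the statistics stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr, ndtri

from .imaging import CTVolume, SegmentationSet, voxel_centers_mm, write_volume, write_labels
from .centralization import distance_map_periphery

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_chest_phantom",
    "preset",
    "write_phantom",
    "CLINICAL_VARIABLES",
    "default_correlation_targets",
    "generate_clinical_table",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters; the defaults are a mid-severity mosaic lung."""

    grid_shape: tuple[int, int, int] = (64, 80, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)   # mm
    body_hu: float = 40.0
    weights: tuple[float, float, float] = (0.2, 0.6, 0.2)   # oligemic, normal, hyperemic
    means: tuple[float, float, float] = (-900.0, -780.0, -620.0)  # HU
    sds: tuple[float, float, float] = (30.0, 40.0, 50.0)    # HU
    blob_scale: float = 10.0          # mm, spatial correlation length of patches
    radial_gradient: float = 0.0      # HU per unit relative hilum-pleura distance
    vein_radius_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must be >= 0 and sum to 1, got {self.weights}")
        if any(s <= 0 for s in self.sds):
            raise ValueError("sds must be positive")
        if self.blob_scale <= 0:
            raise ValueError("blob_scale must be positive")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of a generated phantom."""

    labels: np.ndarray                 # uint8: 0 outside lungs, 1/2/3 compartments
    proportions: dict[str, float]      # realized label fractions over lung voxels
    radial_gradient: float
    vein_entry_mm: dict[str, np.ndarray]   # true hilar point per side
    rel_distance: np.ndarray           # true relative hilum-pleura distance, lung voxels
    n_lung_voxels: int


def _ellipsoid(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = center_mm
    ax, ay, az = semi_mm
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0


def _capsule(shape, spacing, a_mm, b_mm, radius_mm) -> np.ndarray:
    """Voxels within radius of segment a->b (a cylinder with round caps)."""
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    p = np.stack([xx, yy, zz], axis=-1)
    a = np.asarray(a_mm, float)
    d = np.asarray(b_mm, float) - a
    L2 = float(d @ d)
    t = np.clip(((p - a) @ d) / L2, 0.0, 1.0) if L2 > 0 else np.zeros(shape)
    closest = a + t[..., None] * d
    return np.linalg.norm(p - closest, axis=-1) <= radius_mm


def generate_chest_phantom(spec: PhantomSpec
                           ) -> tuple[CTVolume, SegmentationSet, PhantomTruth]:
    """Build a phantom chest volume, its segmentations, and the ground truth."""
    shape = tuple(spec.grid_shape)
    sp = np.asarray(spec.spacing, dtype=float)
    extent = np.asarray(shape) * sp
    rng = np.random.default_rng(spec.seed)

    # --- geometry ---------------------------------------------------------
    lung_semi = extent * np.array([0.17, 0.33, 0.30])
    centers = {
        "left": np.array([0.26, 0.5, 0.5]) * extent,
        "right": np.array([0.74, 0.5, 0.5]) * extent,
    }
    lungs = {s: _ellipsoid(shape, sp, centers[s], lung_semi) for s in centers}
    if np.any(lungs["left"] & lungs["right"]):
        raise ValueError("lungs overlap for this grid/spacing")
    for s, m in lungs.items():
        idx = np.argwhere(m)
        if ((idx.min(axis=0) == 0).any()
                or (idx.max(axis=0) == np.asarray(shape) - 1).any()):
            raise ValueError(f"{s} lung exceeds the grid")
    body = _ellipsoid(shape, sp, 0.5 * extent,
                      extent * np.array([0.47, 0.47, 0.46]))
    body |= lungs["left"] | lungs["right"]

    # --- veins: capsules from inside each medial lung surface to near midline
    midline_x = 0.5 * extent[0]
    veins = np.zeros(shape, dtype=bool)
    vein_entry: dict[str, np.ndarray] = {}
    both_lungs = lungs["left"] | lungs["right"]
    for side, sign in (("left", +1.0), ("right", -1.0)):
        c = centers[side]
        side_veins = np.zeros(shape, dtype=bool)
        # superior and inferior pulmonary veins: two capsules from inside the
        # lung, exiting the medial surface above/below the hilum and
        # converging toward the mediastinum.  Their extrapulmonary centroid
        # (the hilar point) then hugs the medial lung surface, as it should.
        for v in (+1.0, -1.0):
            yoff = v * 0.33 * lung_semi[1]
            x_exit = 0.93 * lung_semi[0]
            a = c + np.array([sign * (x_exit - 12.0), yoff, 0.0])
            b = c + np.array([sign * (x_exit + 1.0), 0.3 * yoff, 0.0])
            if sign * (midline_x - b[0]) < 0:
                raise ValueError(f"{side} vein would cross the midline")
            side_veins |= _capsule(shape, sp, a, b, spec.vein_radius_mm)
        veins |= side_veins
        outside = side_veins & ~both_lungs
        if not outside.any():
            raise ValueError(f"{side} vein has no extrapulmonary segment")
        vein_entry[side] = voxel_centers_mm(np.argwhere(outside), sp).mean(axis=0)

    # --- compartment labels: quantile-thresholded smooth random field -----
    labels = np.zeros(shape, dtype=np.uint8)
    noise = rng.standard_normal(shape)
    fld = ndimage.gaussian_filter(noise, sigma=spec.blob_scale / sp)
    lung_vals = fld[both_lungs]
    cum = np.cumsum(spec.weights)
    lab = np.full(lung_vals.shape, 3, dtype=np.uint8)
    c1, c2 = np.quantile(lung_vals, min(cum[0], 1.0)), np.quantile(lung_vals, min(cum[1], 1.0))
    lab[lung_vals <= c2] = 2
    lab[lung_vals <= c1] = 1
    if spec.weights[0] == 0:
        lab[lab == 1] = 2
    if spec.weights[2] == 0:
        lab[lab == 3] = 2
    labels[both_lungs] = lab
    n_lung = int(both_lungs.sum())
    proportions = {name: float(np.count_nonzero(lab == code) / n_lung)
                   for code, name in ((1, "oligemic"), (2, "normal"), (3, "hyperemic"))}

    # --- true relative hilum-pleura distance (for the gradient term) ------
    rel = np.zeros(shape, dtype=float)
    for side in ("left", "right"):
        m = lungs[side]
        d_p = distance_map_periphery(m, sp)[m]
        idx = np.argwhere(m)
        d_h = np.linalg.norm(voxel_centers_mm(idx, sp) - vein_entry[side], axis=1)
        denom = d_h + d_p
        rel[m] = np.where(denom > 0, d_h / np.where(denom > 0, denom, 1.0), 0.5)

    # --- attenuation ------------------------------------------------------
    hu = np.full(shape, -1000.0)
    hu[body] = spec.body_hu
    means = np.asarray(spec.means, float)
    sds = np.asarray(spec.sds, float)
    lung_mu = means[labels[both_lungs] - 1]
    lung_sd = sds[labels[both_lungs] - 1]
    hu[both_lungs] = rng.normal(lung_mu, lung_sd)
    # gradient centred at mid-distance so compartment means stay put
    hu[both_lungs] += spec.radial_gradient * (rel[both_lungs] - 0.5)
    hu[veins & ~both_lungs] = 150.0   # contrast-filled extrapulmonary veins

    volume = CTVolume(data=hu.astype(np.float32), spacing=tuple(sp),
                      orientation_tag="phantom")
    seg = SegmentationSet(lung_left=lungs["left"], lung_right=lungs["right"],
                          veins=veins, grid_shape=shape)
    truth = PhantomTruth(labels=labels, proportions=proportions,
                         radial_gradient=float(spec.radial_gradient),
                         vein_entry_mm=vein_entry, rel_distance=rel,
                         n_lung_voxels=n_lung)
    return volume, seg, truth


def spmax(spacing) -> float:
    return float(np.max(spacing))


#: Preset study grid: large enough that radial-profile shells average over
#: many mosaic patches, so the imposed gradient dominates patch noise.
_PRESET_GRID = (96, 120, 96)

_PRESETS = {
    # Severe mosaic perfusion with centralization: finely scattered patches
    # with strong attenuation contrast, a large hyperemic+oligemic share,
    # and a strong negative hilum-to-pleura gradient (central hyperemia,
    # peripheral oligemia).
    "severe": dict(grid_shape=_PRESET_GRID,
                   weights=(0.25, 0.45, 0.30),
                   means=(-900.0, -780.0, -620.0), sds=(35.0, 40.0, 50.0),
                   blob_scale=3.0, radial_gradient=-150.0),
    # Minimal perfusion changes: dominant normal compartment, small and
    # coarser oligemic/hyperemic patches, no radial gradient.
    "minimal": dict(grid_shape=_PRESET_GRID,
                    weights=(0.04, 0.90, 0.06),
                    means=(-880.0, -780.0, -680.0), sds=(30.0, 35.0, 30.0),
                    blob_scale=4.5, radial_gradient=0.0),
}


def preset(name: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Named phantom presets emulating severe vs minimal perfusion changes."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return PhantomSpec(seed=seed, **kw)


def write_phantom(out_dir, volume: CTVolume, seg: SegmentationSet,
                  truth: PhantomTruth, spec: PhantomSpec | None = None) -> dict:
    """Write ct.nii.gz, a multi-label seg.nii.gz (1 left, 2 right, 3 veins
    outside lungs), and truth.json; returns the truth record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(volume, out / "ct.nii.gz")
    multilabel = np.zeros(volume.shape, dtype=np.uint8)
    multilabel[seg.lung_left] = 1
    multilabel[seg.lung_right] = 2
    multilabel[seg.veins & ~seg.lungs] = 3
    write_labels(multilabel, volume.spacing, out / "seg.nii.gz")
    record = {
        "proportions": truth.proportions,
        "radial_gradient": truth.radial_gradient,
        "vein_entry_mm": {k: [float(v) for v in p]
                          for k, p in truth.vein_entry_mm.items()},
        "n_lung_voxels": truth.n_lung_voxels,
        "seg_label_counts": {str(i): int(np.count_nonzero(multilabel == i))
                             for i in (1, 2, 3)},
        "compartment_counts": {name: int(round(f * truth.n_lung_voxels))
                               for name, f in truth.proportions.items()},
        "spec": asdict(spec) if spec is not None else None,
    }
    (out / "truth.json").write_text(json.dumps(record, indent=2, sort_keys=True))
    return record


# ---------------------------------------------------------------------------
# Synthetic clinical table (Gaussian copula with prescribed Spearman targets)
# ---------------------------------------------------------------------------

#: The 13 comparison variables: marginal family and parameters.
#: Likert-type radiologist scores take values {0, 1, 2, 3}; physiologic
#: variables use normal or lognormal marginals with plausible scales.
CLINICAL_VARIABLES: dict[str, tuple[str, tuple | None]] = {
    "mosaic_attenuation": ("likert", None),
    "perfusion_centralization": ("likert", None),
    "perfusion_defect_distribution": ("likert", None),
    "subpleural_deficit": ("likert", None),
    "pa_aorta_ratio": ("normal", (1.05, 0.15)),
    "rv_diameter": ("normal", (45.0, 8.0)),
    "ra_area": ("normal", (7.0, 3.0)),
    "six_mwd": ("normal", (398.0, 111.0)),
    "probnp": ("lognormal", (6.9, 1.3)),
    "pamp": ("normal", (45.0, 13.0)),
    "pcwp": ("normal", (10.0, 4.0)),
    "pvr": ("normal", (8.0, 3.5)),
    "sao2": ("normal", (93.5, 4.0)),
}


def default_correlation_targets(metric_cols=()) -> pd.DataFrame:
    """A plausible positive-semi-definite Spearman target matrix.

    Severity variables correlate moderately with each other; if
    ``"prop_normal"`` / ``"slope_mean"`` metric columns are present they
    pick up negative correlations with severity (less normal parenchyma
    and a steeper negative slope in sicker patients).
    """
    cols = list(metric_cols) + list(CLINICAL_VARIABLES)
    S = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)

    def put(a, b, v):
        if a in S.index and b in S.index:
            S.loc[a, b] = S.loc[b, a] = v

    sev = ["mosaic_attenuation", "perfusion_centralization", "probnp",
           "pamp", "pvr", "rv_diameter"]
    for i, a in enumerate(sev):
        for b in sev[i + 1:]:
            put(a, b, 0.35)
    put("six_mwd", "pvr", -0.25)
    put("sao2", "pamp", -0.25)
    for a in sev:
        put("prop_normal", a, -0.45)
        put("slope_mean", a, -0.35)
    put("prop_normal", "slope_mean", 0.4)
    return S


def _latent_from_spearman(S: np.ndarray) -> np.ndarray:
    """Pearson latent correlation giving the target Spearman under a copula."""
    R = 2.0 * np.sin(np.pi * np.asarray(S, float) / 6.0)
    np.fill_diagonal(R, 1.0)
    return R


def _normal_scores(col: np.ndarray) -> np.ndarray:
    ranks = pd.Series(col).rank(method="average").to_numpy()
    return ndtri(ranks / (len(col) + 1.0))


def _apply_marginal(z: np.ndarray, family: str, params) -> np.ndarray:
    if family == "likert":
        return np.minimum(np.floor(ndtr(z) * 4.0), 3.0).astype(int)
    if family == "normal":
        mu, sd = params
        return mu + sd * z
    if family == "lognormal":
        mu, sd = params
        return np.exp(mu + sd * z)
    raise ValueError(f"unknown marginal family {family!r}")


def generate_clinical_table(n_patients: int, seed: int = 0,
                            metrics: pd.DataFrame | None = None,
                            targets: pd.DataFrame | None = None,
                            id_col: str = "patient_id") -> pd.DataFrame:
    """Draw a synthetic clinical table with prescribed rank correlations.

    A Gaussian copula is used: the target Spearman matrix is converted to
    a latent Pearson correlation via ``r = 2 sin(pi * rho_s / 6)``, a
    latent multivariate normal is drawn, and each clinical column is
    produced by a monotone marginal transform (4-level ordinal for the
    radiologist Likert scores, lognormal for proBNP, normal otherwise).

    If ``metrics`` is given (one row per patient), its numeric columns are
    converted to latent normal scores and the clinical latents are drawn
    *conditionally* on them, so metric-clinical target correlations are
    honoured for the actual metric values.

    Raises
    ------
    ValueError
        If the latent correlation matrix is not positive semi-definite
        (the offending eigenvalue is reported).
    """
    rng = np.random.default_rng(seed)
    clin_cols = list(CLINICAL_VARIABLES)
    if metrics is not None:
        met_cols = [c for c in metrics.columns
                    if c != id_col and np.issubdtype(metrics[c].dtype, np.number)]
        if len(metrics) != n_patients:
            raise ValueError("metrics must have one row per patient")
    else:
        met_cols = []
    cols = met_cols + clin_cols

    S = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    if targets is not None:
        shared = [c for c in targets.index if c in S.index]
        for a in shared:
            for b in shared:
                S.loc[a, b] = float(targets.loc[a, b])
    np.fill_diagonal(S.values, 1.0)
    R = _latent_from_spearman(S.to_numpy())
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        raise ValueError(
            f"latent correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {eig.min():.3e})"
        )

    k_m, k_c = len(met_cols), len(clin_cols)
    if k_m:
        Zm = np.column_stack([_normal_scores(metrics[c].to_numpy())
                              for c in met_cols])
        R_mm = np.corrcoef(Zm, rowvar=False).reshape(k_m, k_m)
        R_mm = R_mm + 1e-8 * np.eye(k_m)
        R_mc = R[:k_m, k_m:]
        B = np.linalg.solve(R_mm, R_mc)          # (k_m, k_c)
        cond_mean = Zm @ B
        cond_cov = R[k_m:, k_m:] - R_mc.T @ B
        w, V = np.linalg.eigh(cond_cov)
        A = V * np.sqrt(np.clip(w, 0.0, None))
        Zc = cond_mean + rng.standard_normal((n_patients, k_c)) @ A.T
    else:
        w, V = np.linalg.eigh(R)
        A = V * np.sqrt(np.clip(w, 0.0, None))
        Zc = (rng.standard_normal((n_patients, len(cols))) @ A.T)[:, k_m:]

    out = {}
    if metrics is not None and id_col in metrics.columns:
        out[id_col] = metrics[id_col].to_numpy()
    else:
        out[id_col] = np.arange(n_patients)
    for j, name in enumerate(clin_cols):
        family, params = CLINICAL_VARIABLES[name]
        out[name] = _apply_marginal(Zc[:, j], family, params)
    return pd.DataFrame(out)
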