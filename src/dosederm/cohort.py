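"""Synthetic thorax-phantom cohort generator.

Emulates the statistical structure of a 148-patient breast-VMAT cohort with
~33.1% grade >= 2 radiation dermatitis so every downstream stage (geometry,
feature extraction, selection, modeling, explainability) is exercisable
without patient data.

Per patient the generator builds:

* an axial CT phantom: elliptical-cylinder body with a breast-like lateral
  bulge on the treated side, soft tissue at ~40 HU overlaid with a
  stationary Gaussian-random-field texture whose correlation length is the
  patient's latent ``texture_scale``, lung ellipsoids at ~-750 HU, air at
  -1000 HU;
* a PTV ellipsoid inside the bulge;
* a tangential-style dose field ``D(x) = prescription * hotspot * s(d(x))``
  where ``d`` is the signed Euclidean distance to the PTV surface and ``s``
  a logistic fall-off, with per-patient fall-off parameters so the skin
  dose-volume metrics span a wide range;
* clinical covariates drawn from the reference cohort marginals;
* the outcome label drawn from
  ``P(RD) = sigmoid(b0 + b_age z(age) + b_imn imn + b_v25 z(V25Gy) +
  b_tex z(texture_scale))`` with the intercept auto-calibrated so the mean
  risk matches the target prevalence.

Labels are generated from covariates (DVH / clinical / latent texture), not
raw pixels, so the "signal features" are known ground truth for
selection-recovery tests.  Absolute phantom volumes are desk-scale (smaller
than a real thorax); the generative link, not the absolute cc values, is
the emulation target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from dosederm import dicom, io_rt, tables
from dosederm.core import ClinicalRecord, ImageGrid, StructureMask
from dosederm.geometry import (
    build_body_mask,
    build_skin5mm,
    compute_dvh_features,
    resample_dose_to_ct,
)


@dataclass
class EffectSizes:
    """Log-odds effects of the generative label model (z-scored covariates)."""

    b0: float = 0.0  # recalibrated to the prevalence target
    b_age: float = 0.5
    b_imn: float = 0.8
    b_v25: float = 1.0
    b_texture: float = 0.5


@dataclass
class CohortConfig:
    """The stated world of the synthetic cohort."""

    n_patients: int = 148
    prevalence_target: float = 0.331
    prescription_dose: float = 50.0
    grid_shape: tuple[int, int, int] = (24, 96, 96)  # (z, y, x)
    spacing: tuple[float, float, float] = (2.5, 2.0, 2.0)  # mm
    # covariate marginals of the reference cohort
    p_left: float = 70 / 148
    p_bcs: float = 119 / 148
    p_scf: float = 38 / 148
    p_imn: float = 33 / 148
    p_chemo: float = 74 / 148
    ajcc_probs: tuple[float, ...] = (34 / 148, 46 / 148, 48 / 148, 17 / 148, 3 / 148)
    age_mean: float = 56.0
    age_sd: float = 9.0  # spread not printed in the reference tables
    bmi_mean: float = 24.73
    bmi_sd: float = 3.6
    betas: EffectSizes = field(default_factory=EffectSizes)
    texture_hu_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if not (0 < self.prevalence_target < 1):
            raise ValueError("prevalence_target must lie in (0,1)")
        for p in (self.p_left, self.p_bcs, self.p_scf, self.p_imn, self.p_chemo,
                  *self.ajcc_probs):
            if not (0 <= p <= 1):
                raise ValueError("marginal probabilities must lie in [0,1]")


@dataclass
class SyntheticPatient:
    record: ClinicalRecord
    ct: ImageGrid
    dose: ImageGrid  # on its own (coarser) grid
    body: StructureMask
    ptv: StructureMask
    body_contours: list  # [(z_mm, (N,2) xy polygon)]
    ptv_contours: list
    texture_scale: float
    risk: float = float("nan")
    dvh: dict = field(default_factory=dict)


@dataclass
class Cohort:
    config: CohortConfig
    patients: list[SyntheticPatient]

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.record.rd_grade_ge2 for p in self.patients], dtype=int)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_on_lp(lp: np.ndarray, target: float, tol: float = 0.005,
                     max_iter: int = 200) -> float:
    """Bisection for b0 so mean sigmoid(b0 + lp) hits the target prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        mean = float(sigmoid(mid + lp).mean())
        if abs(mean - target) <= tol:
            return mid
        if mean < target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("calibration failed: tolerance unmet after max iterations")


def calibrate_intercept(betas, covariate_sampler, target: float,
                        n_mc: int = 20000, seed: int = 0) -> float:
    """Monte-Carlo intercept calibration.

    ``covariate_sampler(rng, n)`` must return an ``(n, len(betas))`` design
    matrix; the returned intercept makes the Monte-Carlo mean of
    ``sigmoid(b0 + X @ betas)`` match ``target`` within 0.005.
    """
    if not (0 < target < 1):
        raise ValueError("target must lie in (0,1)")
    betas = np.asarray(betas, dtype=float)
    rng = np.random.default_rng(seed)
    X = np.asarray(covariate_sampler(rng, n_mc), dtype=float)
    lp = X @ betas
    return _calibrate_on_lp(lp, target)


def gaussian_random_field(shape, spacing, correlation_mm: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance Gaussian field via spectral synthesis."""
    noise = rng.standard_normal(shape)
    spectrum = np.fft.fftn(noise)
    k2 = np.zeros(shape)
    for a in range(3):
        k = 2 * np.pi * np.fft.fftfreq(shape[a], d=spacing[a])
        sl = [None, None, None]
        sl[a] = slice(None)
        k2 = k2 + (k[tuple(sl)]) ** 2
    spectrum *= np.exp(-k2 * correlation_mm ** 2 / 4.0)
    fieldv = np.real(np.fft.ifftn(spectrum))
    sd = fieldv.std()
    if sd > 0:
        fieldv = (fieldv - fieldv.mean()) / sd
    return fieldv


def _sample_record(rng: np.random.Generator, cfg: CohortConfig, idx: int) -> ClinicalRecord:
    age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 25, 90))
    bmi = float(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 16, 45))
    return ClinicalRecord(
        patient_id=f"pat{idx:04d}",
        age=age,
        bmi=bmi,
        laterality="left" if rng.random() < cfg.p_left else "right",
        surgery="BCS" if rng.random() < cfg.p_bcs else "TM/MRM",
        ajcc_stage=int(rng.choice(len(cfg.ajcc_probs), p=np.asarray(cfg.ajcc_probs)
                                  / np.sum(cfg.ajcc_probs))),
        scf=bool(rng.random() < cfg.p_scf),
        imn=bool(rng.random() < cfg.p_imn),
        chemotherapy=bool(rng.random() < cfg.p_chemo),
    )


def _build_phantom(rng: np.random.Generator, cfg: CohortConfig,
                   record: ClinicalRecord, texture_scale: float):
    """CT, body/PTV masks and analytic contours for one patient."""
    nz, ny, nx = cfg.grid_shape
    dz, dy, dx = cfg.spacing
    origin = (-(nz - 1) * dz / 2, -(ny - 1) * dy / 2, -(nx - 1) * dx / 2)
    zc = origin[0] + dz * np.arange(nz)
    yc = origin[1] + dy * np.arange(ny)
    xc = origin[2] + dx * np.arange(nx)
    gy, gx = np.meshgrid(yc, xc, indexing="ij")

    extent_y = (ny - 1) * dy
    extent_x = (nx - 1) * dx
    rx = extent_x * rng.uniform(0.33, 0.38)
    ry = extent_y * rng.uniform(0.24, 0.28)
    bulge_amp = rng.uniform(0.14, 0.26) * extent_y
    bulge_width = rng.uniform(0.45, 0.65)  # rad
    side = 1.0 if record.laterality == "left" else -1.0
    theta0 = -np.pi / 2 + side * 0.55  # anterior, shifted to the treated side

    theta = np.arctan2(gy, gx)
    rr = np.hypot(gx, gy)
    r_ell = rx * ry / np.sqrt((ry * np.cos(theta)) ** 2 + (rx * np.sin(theta)) ** 2)
    dtheta = np.angle(np.exp(1j * (theta - theta0)))
    z_mid = zc.mean()
    z_sigma = (zc[-1] - zc[0]) * 0.45

    body = np.zeros(cfg.grid_shape, dtype=bool)
    body_contours = []
    thetas = np.linspace(-np.pi, np.pi, 96, endpoint=False)
    r_ell_1d = rx * ry / np.sqrt((ry * np.cos(thetas)) ** 2 + (rx * np.sin(thetas)) ** 2)
    dtheta_1d = np.angle(np.exp(1j * (thetas - theta0)))
    for k in range(nz):
        amp_k = bulge_amp * np.exp(-((zc[k] - z_mid) ** 2) / (2 * z_sigma ** 2))
        r_k = r_ell + amp_k * np.exp(-dtheta ** 2 / (2 * bulge_width ** 2))
        body[k] = rr <= r_k
        r1d = r_ell_1d + amp_k * np.exp(-dtheta_1d ** 2 / (2 * bulge_width ** 2))
        body_contours.append(
            (float(zc[k]), np.column_stack([r1d * np.cos(thetas), r1d * np.sin(thetas)]))
        )

    # lungs: two ellipsoids inside the posterior body
    gz3, gy3, gx3 = np.meshgrid(zc, yc, xc, indexing="ij")
    lungs = np.zeros(cfg.grid_shape, dtype=bool)
    for sx in (-1.0, 1.0):
        c = (z_mid, 0.25 * ry, sx * 0.45 * rx)
        rads = (0.5 * (zc[-1] - zc[0]), 0.45 * ry, 0.3 * rx)
        lungs |= (((gz3 - c[0]) / rads[0]) ** 2 + ((gy3 - c[1]) / rads[1]) ** 2
                  + ((gx3 - c[2]) / rads[2]) ** 2) <= 1.0
    lungs &= body

    # PTV ellipsoid inside the bulge
    r_at_t0 = rx * ry / np.sqrt((ry * np.cos(theta0)) ** 2 + (rx * np.sin(theta0)) ** 2)
    ptv_r = (rng.uniform(0.35, 0.55) * bulge_amp + 10.0)
    c_dist = r_at_t0 + bulge_amp * 0.5 - ptv_r * 0.4
    c_ptv = (z_mid, c_dist * np.sin(theta0), c_dist * np.cos(theta0))
    ptv_rz = min(ptv_r, 0.4 * (zc[-1] - zc[0]))
    ptv = (((gz3 - c_ptv[0]) / ptv_rz) ** 2 + ((gy3 - c_ptv[1]) / ptv_r) ** 2
           + ((gx3 - c_ptv[2]) / ptv_r) ** 2) <= 1.0
    ptv &= body

    ptv_contours = []
    for k in range(nz):
        f = 1.0 - ((zc[k] - c_ptv[0]) / ptv_rz) ** 2
        if f <= 0:
            continue
        r_k = ptv_r * np.sqrt(f)
        pts = np.column_stack([c_ptv[2] + r_k * np.cos(thetas),
                               c_ptv[1] + r_k * np.sin(thetas)])
        ptv_contours.append((float(zc[k]), pts))

    texture = gaussian_random_field(cfg.grid_shape, cfg.spacing, texture_scale, rng)
    hu = np.full(cfg.grid_shape, -1000.0)
    hu[body] = 40.0 + cfg.texture_hu_sd * texture[body]
    hu[lungs] = -750.0 + 30.0 * texture[lungs]
    hu = np.round(np.clip(hu, -1000, 2000))
    ct = ImageGrid(hu, spacing=cfg.spacing, origin=origin,
                   frame_id=f"frame_{record.patient_id}")
    return (ct, StructureMask("body", body), StructureMask("ptv", ptv),
            body_contours, ptv_contours)


def _build_dose(rng: np.random.Generator, cfg: CohortConfig, ct: ImageGrid,
                ptv: StructureMask) -> ImageGrid:
    """Logistic fall-off dose around the PTV on a 2x coarser in-plane grid."""
    d_out = ndimage.distance_transform_edt(~ptv.mask, sampling=ct.spacing)
    d_in = ndimage.distance_transform_edt(ptv.mask, sampling=ct.spacing)
    signed = d_out - d_in
    tau = rng.uniform(3.0, 8.0)
    d0 = rng.uniform(6.0, 16.0)
    hotspot = rng.uniform(1.0, 1.08)
    dose_ct = cfg.prescription_dose * hotspot * sigmoid(-(signed - d0) / tau)
    # store on a coarser grid so the dose->CT resampling path is exercised
    coarse = dose_ct[:, ::2, ::2]
    dose = ImageGrid(np.round(coarse / 1e-3) * 1e-3,
                     spacing=(ct.spacing[0], ct.spacing[1] * 2, ct.spacing[2] * 2),
                     origin=ct.origin, frame_id=ct.frame_id)
    return dose


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(config: CohortConfig | None = None,
                    out_dir=None) -> Cohort:
    """Generate a full phantom cohort; optionally write the DICOM layout.

    Deterministic in ``config.seed``: the same seed yields byte-identical
    cohorts on disk.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    patient_seeds = rng.integers(0, 2 ** 31 - 1, size=cfg.n_patients)

    patients: list[SyntheticPatient] = []
    for i, ps in enumerate(patient_seeds):
        prng = np.random.default_rng(ps)
        record = _sample_record(prng, cfg, i)
        texture_scale = float(np.exp(prng.normal(np.log(6.0), 0.35)))  # mm
        ct, body, ptv, body_cont, ptv_cont = _build_phantom(prng, cfg, record,
                                                            texture_scale)
        dose = _build_dose(prng, cfg, ct, ptv)
        patients.append(SyntheticPatient(record, ct, dose, body, ptv,
                                         body_cont, ptv_cont, texture_scale))

    # DVH through the real geometry stack (recovery hook for downstream stages)
    for p in patients:
        dose_ct = resample_dose_to_ct(p.dose, p.ct)
        body = build_body_mask(p.ct)
        skin = build_skin5mm(body, p.ct.spacing)
        p.dvh = compute_dvh_features(dose_ct, skin, p.ptv,
                                     cfg.prescription_dose).as_dict()

    v25 = np.array([p.dvh["skin5mm_V25Gy"] for p in patients])
    ages = np.array([p.record.age for p in patients])
    imn = np.array([p.record.imn for p in patients], dtype=float)
    tex = np.array([p.texture_scale for p in patients])
    b = cfg.betas
    lp = (b.b_age * _zscore(ages) + b.b_imn * imn + b.b_v25 * _zscore(v25)
          + b.b_texture * _zscore(tex))
    b0 = _calibrate_on_lp(lp, cfg.prevalence_target)
    risks = sigmoid(b0 + lp)
    label_rng = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))
    draws = label_rng.random(cfg.n_patients)
    for p, r, u in zip(patients, risks, draws):
        p.risk = float(r)
        p.record.rd_grade_ge2 = bool(u < r)

    cohort = Cohort(cfg, patients)
    if out_dir is not None:
        write_dicom_cohort(cohort, out_dir)
    return cohort


def write_dicom_cohort(cohort: Cohort, out_dir) -> None:
    """Emit the cohort exchange layout: DICOM per patient + CSV + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dicom._UID_COUNTER[0] = 0  # deterministic UIDs for byte-identical output
    for p in cohort.patients:
        pdir = out_dir / p.record.patient_id
        io_rt.write_ct_series(p.ct, pdir, p.record.patient_id)
        io_rt.write_rtdose(p.dose, pdir / "rd.dcm")
        io_rt.write_rtstruct({"body": p.body_contours, "ptv": p.ptv_contours},
                             pdir / "rs.dcm", frame_id=p.ct.frame_id)
    io_rt.write_clinical_csv([p.record for p in cohort.patients],
                             out_dir / "clinical.csv")
    cfg = cohort.config
    io_rt.write_manifest(out_dir / "manifest.json", {
        "n_patients": cfg.n_patients,
        "prescription_dose": cfg.prescription_dose,
        "prevalence_target": cfg.prevalence_target,
        "grid_shape": list(cfg.grid_shape),
        "spacing": list(cfg.spacing),
        "seed": cfg.seed,
        "patients": [p.record.patient_id for p in cohort.patients],
    })


def sample_population(cfg: CohortConfig, n: int, seed: int = 0):
    """Covariate-level fast path: draw (clinical, DVH, latent) + labels.

    Draws DVH metrics from the reference-cohort marginal summaries instead
    of building phantom images; the generative label link is identical to
    :func:`generate_cohort`.  Intended for large-n statistical checks of
    the selection and modeling stages.

    Returns ``(records, dvh_frame_dict, labels, risks)``.
    """
    rng = np.random.default_rng(seed)
    records = [_sample_record(rng, cfg, i) for i in range(n)]
    # correlated DVH draws: one latent exposure factor drives all V_x levels
    exposure = rng.standard_normal(n)
    dvh: dict[str, np.ndarray] = {}
    for name, (mean, sd, *_rest) in tables.TABLE2_SUMMARIES.items():
        noise = rng.standard_normal(n)
        vals = mean + sd * (0.8 * exposure + 0.6 * noise)
        dvh[name] = np.clip(vals, 0.0, None)
    tex = np.exp(rng.normal(np.log(6.0), 0.35, size=n))
    ages = np.array([r.age for r in records])
    imn = np.array([r.imn for r in records], dtype=float)
    b = cfg.betas
    lp = (b.b_age * _zscore(ages) + b.b_imn * imn
          + b.b_v25 * _zscore(dvh["skin5mm_V25Gy"]) + b.b_texture * _zscore(tex))
    b0 = _calibrate_on_lp(lp, cfg.prevalence_target) if np.ptp(lp) > 0 else (
        np.log(cfg.prevalence_target / (1 - cfg.prevalence_target)))
    risks = sigmoid(b0 + lp)
    labels = (rng.random(n) < risks).astype(int)
    for r, y in zip(records, labels):
        r.rd_grade_ge2 = bool(y)
    return records, dvh, labels, risks
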