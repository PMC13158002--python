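"""Seeded synthetic cohort generator.

Physiological model: each subject's gBOLD signal is a unit-variance
narrowband Gaussian process (white noise band-passed around ``f0``); the
CSF signal is the normalized negative forward-difference derivative of
gBOLD, delayed by ``round(delay_s / tr)`` samples, plus white noise whose
SD is calibrated so the expected correlation at the +4 s lag equals the
subject's assigned coupling.  For a narrowband process centred at f0 the
noise-free cross-correlation minimum sits near ``1/(4*f0) - delay`` and
the derivative-coupling maximum at exactly ``-delay`` on the lag grid,
reproducing the -4 s / +4 s / -2 s peak structure of the real data.

The bandwidth default (0.05 Hz) is wide enough that the autocorrelation
envelope decay breaks the half-sample tie between the +4 s and +6 s grid
lags; much narrower bands make the sampled minimum location unstable.
The additive CSF noise is band-limited to the analysis passband
(0.01-0.1 Hz) so that downstream temporal filtering neither removes noise
nor biases the calibrated coupling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .cohort import SubjectRecord
from .io import MaskVolume, MotionTrace, QcPolicy, Volume4D, write_mask, write_motion_params, write_volume
from .preproc import TimeSeries

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Cohort",
    "generate_signal_pair",
    "calibrate_noise",
    "ideal_coupling",
    "generate_cohort",
    "render_subject",
    "write_study",
]


@dataclass
class SyntheticConfig:
    """Every generator knob, with ground-truth bookkeeping for recovery tests."""

    n_bqd: int = 29
    n_hc: int = 37
    n_volumes: int = 240  # pre-discard
    tr: float = 2.0
    f0: float = 1.0 / 24.0
    bandwidth: float = 0.05
    delay_s: float = 2.0
    metric_lag_s: float = 4.0
    noise_band: tuple[float, float] = (0.01, 0.1)
    target_coupling_bqd: float = -0.240
    target_coupling_hc: float = -0.111
    coupling_sd_bqd: float = 0.200
    coupling_sd_hc: float = 0.225
    duration_coupling_r: float = 0.43
    grid: tuple[int, int, int] = (16, 16, 8)
    voxel_size: tuple[float, float, float] = (3.5, 3.5, 3.5)
    voxel_noise_sd: float = 0.2
    signal_scale: float = 1.0
    motion_violation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nyquist = 0.5 / self.tr
        if not 0 < self.f0 - self.bandwidth / 2:
            raise ValueError("band lower edge must be positive")
        if not self.f0 + self.bandwidth / 2 < nyquist:
            raise ValueError("band upper edge must be below Nyquist")
        self.noise_band = tuple(float(v) for v in self.noise_band)
        if not 0 < self.noise_band[0] < self.noise_band[1] < nyquist:
            raise ValueError(f"noise_band {self.noise_band} invalid for Nyquist {nyquist}")
        for t in (self.target_coupling_bqd, self.target_coupling_hc):
            if not abs(t) < 1:
                raise ValueError(f"|target coupling| must be < 1, got {t}")
        if self.n_bqd < 2 or self.n_hc < 2:
            raise ValueError("group sizes must be >= 2")
        if self.n_volumes < 3:
            raise ValueError("n_volumes must be >= 3")
        self.grid = tuple(int(g) for g in self.grid)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def delay_samples(self) -> int:
        return int(round(self.delay_s / self.tr))


@dataclass
class GroundTruth:
    """Per-subject generator truth plus the parameters that produced it."""

    subjects: dict[str, dict]
    params: dict


@dataclass
class Cohort:
    records: list[SubjectRecord]
    signals: dict[str, tuple[TimeSeries, TimeSeries]]
    motion: dict[str, MotionTrace]
    ground_truth: GroundTruth
    config: SyntheticConfig


_FILTER_PAD = 400


def _narrowband(rng: np.random.Generator, n: int, dt: float, f0: float, bw: float) -> np.ndarray:
    """Unit-variance narrowband Gaussian process of length n."""
    white = rng.standard_normal(n + 2 * _FILTER_PAD)
    sos = sps.butter(4, [f0 - bw / 2, f0 + bw / 2], btype="bandpass", fs=1.0 / dt, output="sos")
    g = sps.sosfiltfilt(sos, white)[_FILTER_PAD : _FILTER_PAD + n]
    return (g - g.mean()) / g.std()


def generate_signal_pair(
    config: SyntheticConfig,
    subject_coupling: float,
    rng: np.random.Generator,
    noise_sd: float | None = None,
) -> tuple[TimeSeries, TimeSeries]:
    """One subject's (gBOLD, CSF) pair with expected r(+4 s) = subject_coupling.

    ``subject_coupling = 0`` produces an independent CSF signal (null
    subjects).  A positive coupling flips the sign of the derivative
    component; the noise SD defaults to the calibrated value for the
    requested coupling.
    """
    n = config.n_volumes
    dt = config.tr
    m = config.delay_samples
    if abs(m * dt - config.delay_s) > 1e-9:
        import warnings

        warnings.warn(
            f"delay {config.delay_s} s is not a multiple of tr={dt} s; "
            f"rounded to {m * dt} s",
            stacklevel=2,
        )
    if subject_coupling == 0.0:
        g = _narrowband(rng, n, dt, config.f0, config.bandwidth)
        c = _narrowband(rng, n, dt, config.f0, config.bandwidth)
        return TimeSeries(g, dt), TimeSeries(c, dt)

    g_long = _narrowband(rng, n + m + 1, dt, config.f0, config.bandwidth)
    nd = -np.diff(g_long) / dt  # forward difference, length n + m
    g = g_long[m : m + n]
    c_sig = nd[:n]  # = -g'(t) of g_long => derivative of g delayed by m samples
    c_sig = (c_sig - c_sig.mean()) / c_sig.std()
    if subject_coupling > 0:
        c_sig = -c_sig
    if noise_sd is None:
        noise_sd = calibrate_noise(config, subject_coupling, refine=False)
    lo, hi = config.noise_band
    noise = _narrowband(rng, n, dt, (lo + hi) / 2, hi - lo)
    c = c_sig + noise_sd * noise
    c = (c - c.mean()) / c.std()
    return TimeSeries(g, dt), TimeSeries(c, dt)


_IDEAL_CACHE: dict[tuple, float] = {}


def _fixed_lag_r(g: np.ndarray, c: np.ndarray, k: int) -> float:
    x, y = g[k:], c[: c.size - k]
    return float(np.corrcoef(x, y)[0, 1])


def ideal_coupling(config: SyntheticConfig, n_rep: int = 400, inner_seed: int = 12345) -> float:
    """Expected noise-free correlation at the metric lag, estimated once by
    simulation (cached per generator geometry; fixed inner seed)."""
    key = (config.n_volumes, config.tr, config.f0, config.bandwidth,
           config.delay_samples, config.metric_lag_s, n_rep, inner_seed)
    if key not in _IDEAL_CACHE:
        rng = np.random.default_rng(inner_seed)
        k = int(round(config.metric_lag_s / config.tr))
        n, m = config.n_volumes, config.delay_samples
        vals = np.empty(n_rep)
        for i in range(n_rep):
            g_long = _narrowband(rng, n + m + 1, config.tr, config.f0, config.bandwidth)
            nd = -np.diff(g_long) / config.tr
            g = g_long[m : m + n]
            c = nd[:n]
            vals[i] = _fixed_lag_r(g, (c - c.mean()) / c.std(), k)
        _IDEAL_CACHE[key] = float(vals.mean())
    return _IDEAL_CACHE[key]


def calibrate_noise(
    config: SyntheticConfig,
    target_r: float,
    tol: float = 0.01,
    refine: bool = True,
    n_rep: int = 300,
    inner_seed: int = 54321,
) -> float:
    """Noise SD sigma such that the expected observed r at the metric lag
    equals ``target_r``.

    Initialization uses the attenuation relation
    ``r_obs = r_ideal / sqrt(1 + sigma^2)``; with ``refine`` the value is
    polished by bisection against simulated estimates (fixed inner seed).
    """
    if abs(target_r) <= 0.01:
        raise ValueError(f"|target_r| must exceed 0.01, got {target_r}")
    r_ideal = ideal_coupling(config)
    if abs(target_r) > abs(r_ideal):
        raise ValueError(
            f"target {target_r} unattainable: noise-free coupling magnitude is "
            f"{abs(r_ideal):.3f}"
        )
    sigma0 = float(np.sqrt((r_ideal / target_r) ** 2 - 1.0))
    if not refine:
        return sigma0

    k = int(round(config.metric_lag_s / config.tr))

    def mean_r(sigma: float) -> float:
        rng = np.random.default_rng(inner_seed)
        vals = np.empty(n_rep)
        for i in range(n_rep):
            g, c = generate_signal_pair(config, target_r, rng, noise_sd=sigma)
            vals[i] = _fixed_lag_r(g.values, c.values, k)
        return float(vals.mean())

    lo, hi = 0.0, max(4.0 * sigma0, 1.0)
    sigma = sigma0
    for _ in range(30):
        r = mean_r(sigma)
        if abs(r - target_r) <= tol:
            return sigma
        # larger sigma -> |r| smaller; bisect on magnitude
        if abs(r) > abs(target_r):
            lo = sigma
        else:
            hi = sigma
        sigma = 0.5 * (lo + hi)
    return sigma


def _truncated_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, low, high)


def _draw_targets(rng, mean, sd, max_mag, size):
    """Coupling targets: normal draws, magnitude clipped into [0.011, max_mag]."""
    raw = _truncated_normal(rng, mean, sd, -0.95, 0.95, size)
    sign = np.where(raw < 0, -1.0, 1.0)
    mag = np.clip(np.abs(raw), 0.011, max_mag)
    return sign * mag


def _motion_trace(rng, n_volumes: int, violate: bool, policy: QcPolicy) -> MotionTrace:
    # slow random drift well under the limits; violators get one spike
    t = np.arange(n_volumes)
    trans = np.cumsum(rng.normal(0, 0.01, (n_volumes, 3)), axis=0)
    trans -= trans.mean(axis=0)
    trans = np.clip(trans, -0.8, 0.8)
    rot = np.cumsum(rng.normal(0, 0.008, (n_volumes, 3)), axis=0)
    rot -= rot.mean(axis=0)
    rot = np.clip(rot, -0.8, 0.8)
    if violate:
        axis = int(rng.integers(3))
        vol = int(rng.integers(n_volumes // 2, n_volumes))
        if rng.random() < 0.5:
            trans[vol, axis] = policy.trans_limit_mm * rng.uniform(1.1, 1.8)
        else:
            rot[vol, axis] = policy.rot_limit_deg * rng.uniform(1.1, 1.8)
    return MotionTrace(translations=trans, rotations_deg=rot)


def generate_cohort(config: SyntheticConfig | None = None) -> Cohort:
    """Generate a full cohort: signals, clinical table, motion traces, truth.

    Clinical scores follow the study's published group moments: BQD
    duration N(15.3, 7.4) truncated positive and tied linearly to the
    subject's ideal coupling to reach the configured duration-coupling
    correlation; BQDS N(8.8, 2.7) truncated > 4; daily dose N(6.1, 7.2)
    truncated positive; HAMA/HAMD integer scores in 0..7.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    r_ideal = ideal_coupling(config)
    max_mag = min(0.95, abs(r_ideal) - 0.02)

    groups = (
        ("BQD", config.n_bqd, config.target_coupling_bqd, config.coupling_sd_bqd, 13 / 29),
        ("HC", config.n_hc, config.target_coupling_hc, config.coupling_sd_hc, 5 / 37),
    )
    records: list[SubjectRecord] = []
    signals: dict[str, tuple[TimeSeries, TimeSeries]] = {}
    motion: dict[str, MotionTrace] = {}
    truth_subjects: dict[str, dict] = {}
    policy = QcPolicy()

    n_total = config.n_bqd + config.n_hc
    n_violate = int(round(config.motion_violation_fraction * n_total))
    violate_idx = set(rng.choice(n_total, size=n_violate, replace=False).tolist())

    idx = 0
    for group, n_grp, mu, sd, p_male in groups:
        targets = _draw_targets(rng, mu, sd, max_mag, n_grp)
        z = (targets - mu) / sd
        rho = config.duration_coupling_r
        dur_noise = rng.standard_normal(n_grp)
        durations = 15.3 + 7.4 * (rho * z + np.sqrt(max(0.0, 1 - rho**2)) * dur_noise)
        durations = np.clip(durations, 0.5, None)
        bqds = _truncated_normal(rng, 8.8, 2.7, 4.5, 20.0, n_grp)
        dose = _truncated_normal(rng, 6.1, 7.2, 0.5, 40.0, n_grp)
        if group == "BQD":
            ages = _truncated_normal(rng, 42.0, 8.0, 18.0, 60.0, n_grp)
            edu = _truncated_normal(rng, 10.0, 2.5, 1.0, 22.0, n_grp)
        else:
            ages = _truncated_normal(rng, 36.0, 10.0, 18.0, 60.0, n_grp)
            edu = _truncated_normal(rng, 14.0, 3.0, 1.0, 22.0, n_grp)
        sexes = np.where(rng.random(n_grp) < p_male, "M", "F")
        hama = rng.integers(0, 8, n_grp)
        hamd = rng.integers(0, 8, n_grp)

        for i in range(n_grp):
            sid = f"sub-{idx + 1:03d}"
            sigma = calibrate_noise(config, float(targets[i]), refine=False)
            g, c = generate_signal_pair(config, float(targets[i]), rng, noise_sd=sigma)
            signals[sid] = (g, c)
            violates = idx in violate_idx
            motion[sid] = _motion_trace(rng, config.n_volumes, violates, policy)
            is_bqd = group == "BQD"
            records.append(
                SubjectRecord(
                    id=sid,
                    group=group,
                    sex=str(sexes[i]),
                    age=round(float(ages[i]), 1),
                    education=round(float(edu[i]), 1),
                    bqds=round(float(bqds[i]), 1) if is_bqd else None,
                    duration=round(float(durations[i]), 1) if is_bqd else None,
                    daily_dose=round(float(dose[i]), 1) if is_bqd else None,
                    hama14=int(hama[i]),
                    hamd24=int(hamd[i]),
                )
            )
            truth_subjects[sid] = {
                "ideal_coupling": float(targets[i]),
                "noise_sd": float(sigma),
                "motion_violation": bool(violates),
                "duration": float(durations[i]) if is_bqd else None,
            }
            idx += 1

    truth = GroundTruth(
        subjects=truth_subjects,
        params={**asdict(config), "ideal_noise_free_coupling": r_ideal},
    )
    return Cohort(records=records, signals=signals, motion=motion,
                  ground_truth=truth, config=config)


def render_subject(
    g: TimeSeries,
    c: TimeSeries,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[Volume4D, MaskVolume, MaskVolume]:
    """Embed one subject's signals into a 4D volume.

    Grey-matter voxels (a central block away from the bottom slice) carry
    the gBOLD signal plus independent voxel noise; CSF voxels (a block in
    acquisition slice 0) carry the CSF signal; everything else is noise.
    """
    nx, ny, nz = config.grid
    if nz < 4 or nx < 8 or ny < 8:
        raise ValueError(f"grid {config.grid} too small to place both masks")
    n = len(g)
    gm = np.zeros(config.grid, dtype=bool)
    gm[nx // 4 : 3 * nx // 4, ny // 4 : 3 * ny // 4, max(1, nz // 3) : nz - 1] = True
    csf = np.zeros(config.grid, dtype=bool)
    csf[3 * nx // 8 : 5 * nx // 8, 3 * ny // 8 : 5 * ny // 8, 0] = True
    if (gm & csf).any():
        raise ValueError("grey-matter and CSF masks overlap")

    data = rng.normal(0.0, config.voxel_noise_sd, (*config.grid, n))
    data[gm] += config.signal_scale * g.values
    data[csf] += config.signal_scale * c.values
    vol = Volume4D(data=data, voxel_size=config.voxel_size, tr=config.tr)
    return (
        vol,
        MaskVolume(gm, config.voxel_size),
        MaskVolume(csf, config.voxel_size),
    )


def write_study(cohort: Cohort, outdir: str | Path) -> dict:
    """Write a complete synthetic study directory; returns the manifest.

    Layout: per-subject ``<id>_func.nii`` and ``rp_<id>.txt`` (SPM radians
    dialect), shared ``gm_mask.nii`` / ``csf_mask.nii``, ``cohort.tsv``,
    ``ground_truth.json`` and the generator config as ``config.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = cohort.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_777]))
    manifest: dict = {"subjects": [], "seed": config.seed}
    masks_written = False
    for rec in cohort.records:
        g, c = cohort.signals[rec.id]
        vol, gm_mask, csf_mask = render_subject(g, c, config, rng)
        if not masks_written:
            write_mask(gm_mask, outdir / "gm_mask.nii")
            write_mask(csf_mask, outdir / "csf_mask.nii")
            masks_written = True
        write_volume(vol, outdir / f"{rec.id}_func.nii")
        write_motion_params(cohort.motion[rec.id], outdir / f"rp_{rec.id}.txt")
        manifest["subjects"].append(rec.id)

    frame = pd.DataFrame([asdict(r) for r in cohort.records]).drop(columns=["coupling", "qc_pass"])
    frame.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump({"subjects": cohort.ground_truth.subjects,
                   "params": cohort.ground_truth.params}, fh, indent=2)
    cfg_dict = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
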