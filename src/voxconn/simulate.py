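"""Synthetic resting-state BOLD generator with plantable network effects.

The generator emulates the data a voxel-level connectivity study records from
a single cortical region: per-voxel time series that are mixtures of

* shared band-limited latent signals (0.01-0.09 Hz sums of sinusoids) whose
  mixing weights decay exponentially with lattice distance from seeded
  community centres -- this produces the spatially structured correlation
  matrix that makes percolation thresholding and clustering meaningful;
* nuisance components (slow drift, motion-coupled signal, WM/CSF traces)
  that the preprocessing stage is expected to remove;
* AR(1) voxel noise (phi = 0.3 by default) for the prewhitening stage.

Connectivity effects are planted by *re-mixing* the existing latents (the
band-limited signal space of a session is only ~50-dimensional and cannot
carry extra independent signals): target voxels' mixing profiles are pulled
toward a reference profile by a fraction solved from the generator's own
covariance model, so that the expected pairwise correlation among target
voxels rises by a requested delta while per-voxel signal power (and hence
AR structure and prewhitening behaviour) is exactly preserved.  Two effect
kinds mirror the two phenomena of interest: ``local_coupling`` (profiles
converge within a compact target subregion, strengthening local
synchronization) and ``long_range`` (target profiles acquire components of
distal partner voxels, creating functional shortcuts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal
from scipy.ndimage import gaussian_filter1d

from .roi import RoiMask, make_roi, select_subregion

__all__ = [
    "BoldSeries", "NuisanceSet", "EffectSpec", "StudyDesign", "StudyData",
    "simulate_session", "simulate_study", "default_study_design",
]

SESSIONS = ("anodal", "cathodal", "sham")
TIMES = ("before", "after")


@dataclass
class BoldSeries:
    """Voxels x timepoints BOLD signal matrix tied to an ROI."""

    data: np.ndarray
    tr_seconds: float = 1.8
    roi: RoiMask | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 3:
            raise ValueError("data must be (voxels, timepoints>=3)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.roi is not None and self.data.shape[0] != self.roi.n_voxels:
            raise ValueError("row count must equal roi.n_voxels")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class NuisanceSet:
    """Nine nuisance regressors: six motion traces (3 translations in mm,
    3 rotations in degrees), WM mean, CSF mean and the global signal."""

    regressors: np.ndarray
    names: tuple = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
                    "wm", "csf", "global")

    def __post_init__(self):
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2 or self.regressors.shape[0] != 9:
            raise ValueError("regressors must be a 9 x timepoints matrix")

    @property
    def motion(self) -> np.ndarray:
        return self.regressors[:6]

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[1]


@dataclass(frozen=True)
class EffectSpec:
    """A planted connectivity effect confined to a target subregion."""

    kind: str = "none"                      # none | local_coupling | long_range
    target_voxels: tuple = ()               # node indices into the RoiMask
    coupling_delta: float = 0.0             # expected pairwise-r increase
    n_shortcut_partners: int = 3            # long_range only
    baseline_scaling: float | None = None   # per-subject multiplier, set by study
    local_radius_vox: float = 3.0           # local_coupling neighbourhood radius
    boundary_decoupling: float = 1.8        # local_coupling target/surround trade-off

    def __post_init__(self):
        if self.kind not in ("none", "local_coupling", "long_range"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.coupling_delta < 0 or self.coupling_delta >= 1:
            raise ValueError("coupling_delta must be in [0, 1)")
        if self.kind == "none" and self.coupling_delta != 0:
            raise ValueError("kind='none' requires coupling_delta = 0")
        object.__setattr__(self, "target_voxels",
                           tuple(int(v) for v in self.target_voxels))


@dataclass(frozen=True)
class StudyDesign:
    """Fully crossed subjects x session x time design.

    Defaults follow a 14-subject, three-session (anodal / cathodal / sham),
    before/after stimulation protocol: 84 resting-state datasets in total.
    ``sham`` cells and all ``before`` cells must carry a null effect.
    """

    n_subjects: int = 14
    sessions: tuple = SESSIONS
    times: tuple = TIMES
    effect_by_cell: dict = field(default_factory=dict)
    seed: int = 0
    subject_heterogeneity: float = 0.2      # spread of baseline coupling strength
    effect_heterogeneity: float = 0.0       # spread of per-subject effect size
    baseline_effect_rho: float = 0.0        # latent corr(baseline, effect size)

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for (session, time), eff in self.effect_by_cell.items():
            if session not in self.sessions or time not in self.times:
                raise ValueError(f"cell {(session, time)} outside the design")
            if (time == "before" or session == "sham") and eff.kind != "none":
                raise ValueError("sham and 'before' cells must carry kind='none'")

    def effect_for(self, session: str, time: str) -> EffectSpec:
        return self.effect_by_cell.get((session, time), EffectSpec())

    @property
    def n_datasets(self) -> int:
        return self.n_subjects * len(self.sessions) * len(self.times)


def default_study_design(n_subjects: int = 14, target_voxels=(), seed: int = 0,
                         coupling_delta: float = 0.15,
                         anodal_coupling_delta: float = 0.25,
                         n_shortcut_partners: int = 3) -> StudyDesign:
    """The study-like default: cathodal stimulation plants a local-coupling
    increase, anodal plants long-range shortcuts, sham is null.

    The anodal (shortcut) delta defaults higher than the cathodal one:
    shortcut link correlations start near zero and must clear the group
    percolation threshold (~0.35) before any graph shortcut exists.
    """
    effects = {
        ("cathodal", "after"): EffectSpec(
            kind="local_coupling", target_voxels=tuple(target_voxels),
            coupling_delta=coupling_delta),
        ("anodal", "after"): EffectSpec(
            kind="long_range", target_voxels=tuple(target_voxels),
            coupling_delta=anodal_coupling_delta,
            n_shortcut_partners=n_shortcut_partners),
    }
    return StudyDesign(n_subjects=n_subjects, effect_by_cell=effects, seed=seed)


# --------------------------------------------------------------------------
# latent signal machinery


def band_capacity(n_timepoints: int, tr: float, low_hz: float = 0.01,
                  high_hz: float = 0.09) -> int:
    """Number of orthogonal band-limited signals a session can carry.

    The in-band signal space is spanned by the DFT sine/cosine pairs whose
    frequencies k/(T*tr) fall inside the passband -- roughly
    2*(high-low)*T*tr dimensions (about 50 for a 175-volume, TR 1.8 s
    acquisition with a 0.01-0.09 Hz band).  No session can contain more
    mutually independent band-limited latent signals than this.
    """
    k_lo = max(1, int(np.ceil(low_hz * n_timepoints * tr)))
    k_hi = min(n_timepoints // 2 - 1,
               int(np.floor(high_hz * n_timepoints * tr)))
    if k_hi < k_lo:
        raise ValueError("passband too narrow for this acquisition")
    return 2 * (k_hi - k_lo + 1)


def _band_limited_latents(n_latents: int, n_timepoints: int, tr: float,
                          rng: np.random.Generator,
                          low_hz: float = 0.01, high_hz: float = 0.09
                          ) -> np.ndarray:
    """Orthonormal band-limited latent time courses, (T, C), unit variance.

    The latents are a random rotation of the exact in-band Fourier basis
    (DFT sine/cosine pairs inside the passband): exactly orthogonal over the
    sample grid, exactly band-limited, with flat expected spectra.  The
    sample covariance of any weighted mixture W @ latents.T is therefore
    exactly W W^T, and session-to-session spectral variation is minimal.
    """
    k_lo = max(1, int(np.ceil(low_hz * n_timepoints * tr)))
    k_hi = min(n_timepoints // 2 - 1,
               int(np.floor(high_hz * n_timepoints * tr)))
    d = 2 * (k_hi - k_lo + 1)
    if n_latents > d:
        raise ValueError(
            f"cannot fit {n_latents} independent band-limited latents into "
            f"a {d}-dimensional passband (T={n_timepoints}, TR={tr})")
    t = np.arange(n_timepoints)
    basis = np.empty((n_timepoints, d))
    for m, k in enumerate(range(k_lo, k_hi + 1)):
        basis[:, 2 * m] = np.cos(2 * np.pi * k * t / n_timepoints)
        basis[:, 2 * m + 1] = np.sin(2 * np.pi * k * t / n_timepoints)
    basis *= np.sqrt(2.0 / n_timepoints)          # orthonormal columns
    g = rng.standard_normal((d, n_latents))
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))            # fix QR sign ambiguity for determinism
    return (basis @ q) * np.sqrt(n_timepoints)    # zero mean, unit variance


def _community_weights(roi: RoiMask, rng: np.random.Generator,
                       length_scale_vox: float, center_spacing_vox: float,
                       signal_sd: float, max_centers: int | None = None
                       ) -> np.ndarray:
    """Mixing weights (N x C): one latent per community centre, weight
    decaying exponentially with lattice distance from the centre.

    Rows are normalized so every voxel carries signal variance
    ``signal_sd**2``; the pairwise model correlation of two voxels is then
    (cosine similarity of their weight profiles) x (shared signal fraction),
    which decays smoothly with lattice distance.  ``max_centers`` caps the
    community count at the session's band capacity.
    """
    coords = roi.voxel_coords.astype(float)
    n_centers = max(3, int(round(roi.n_voxels / center_spacing_vox**3)))
    if max_centers is not None:
        n_centers = min(n_centers, max_centers)
    centers = coords[rng.choice(roi.n_voxels, size=n_centers, replace=False)]
    d = np.sqrt(((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    w = np.exp(-d / length_scale_vox)
    w *= signal_sd / np.linalg.norm(w, axis=1, keepdims=True)
    return w


def _ar1_noise(shape, phi, sd, rng):
    white = rng.standard_normal(shape) * sd
    return signal.lfilter([1.0], [1.0, -phi], white, axis=-1)


def _inband_noise_fraction(phi: float, tr: float, low_hz: float, high_hz: float) -> float:
    """Fraction of AR(1) noise variance inside the analysis passband."""
    f = np.linspace(0, 0.5 / tr, 2049)
    spec = 1.0 / (1 - 2 * phi * np.cos(2 * np.pi * f * tr) + phi**2)
    total = np.trapezoid(spec, f)
    inband = np.trapezoid(np.where((f >= low_hz) & (f <= high_hz), spec, 0.0), f)
    return float(inband / total)


def _model_correlation(weights: np.ndarray, noise_var: float) -> np.ndarray:
    cov = weights @ weights.T
    var = np.diag(cov) + noise_var
    return cov / np.sqrt(np.outer(var, var))


def _apply_effect(roi, effect, weights, noise_var, rng,
                  min_shortcut_dist_vox=4.0, saturate=False):
    """Plant a connectivity effect by mixing weight profiles.

    Effects never add latent signals (the band could not carry them); they
    re-mix the existing ones.  Each target voxel's mixing profile is pulled
    toward a reference profile by a fraction beta and then renormalized to
    its original signal power:

    * ``local_coupling``: the reference is the mean profile of the target
      voxels within ``local_radius_vox`` of the voxel -- profiles of nearby
      target voxels converge, raising local synchronization;
    * ``long_range``: the reference is the mean profile of
      ``n_shortcut_partners`` distal non-target voxels (chosen once per
      architecture), creating functional shortcuts.

    beta is solved from the covariance model so the mean pairwise
    correlation over the affected pairs (all within-target pairs for
    local_coupling, the shortcut links for long_range) exceeds the
    unmodified model by ``coupling_delta`` (times ``baseline_scaling``).
    Power renormalization makes the effect invisible to per-voxel
    marginals: variance, AR structure and prewhitening gains stay at their
    null values, so the effect cannot leak into global graph density.

    Returns ``(mixed_weights, info)``.
    """
    n = roi.n_voxels
    delta = effect.coupling_delta
    if effect.baseline_scaling is not None:
        delta = float(np.clip(delta * effect.baseline_scaling, 0.0, 0.95))
    tgt = np.asarray(effect.target_voxels, dtype=int)
    if effect.kind == "none" or delta == 0 or len(tgt) == 0:
        return weights, {}
    if tgt.max() >= n:
        raise ValueError("target_voxels outside the ROI")

    cov0 = weights @ weights.T
    var0 = np.diag(cov0) + noise_var

    if effect.kind == "local_coupling":
        # reference profile = local within-target mean, minus a dose of the
        # surrounding non-target profiles: synchronization is *redistributed*
        # from the target's boundary into the target (local connectedness
        # rises while the number of supra-threshold connections per voxel
        # stays roughly flat -- the intended phenomenon).
        all_d = np.sqrt(((roi.voxel_coords[tgt][:, None, :].astype(float)
                          - roi.voxel_coords[None, :, :].astype(float)) ** 2
                         ).sum(axis=2))
        in_tgt = np.isin(np.arange(n), tgt)
        nbh = (all_d <= effect.local_radius_vox) & in_tgt[None, :]
        out = (all_d <= effect.local_radius_vox) & ~in_tgt[None, :]
        ref = (nbh @ weights) / nbh.sum(axis=1, keepdims=True)
        has_out = out.sum(axis=1) > 0
        out_ref = np.zeros_like(ref)
        out_ref[has_out] = (out[has_out] @ weights) \
            / out[has_out].sum(axis=1, keepdims=True)
        ref = ref - effect.boundary_decoupling * out_ref
        ii, jj = np.triu_indices(len(tgt), k=1)
        ei, ej = tgt[ii], tgt[jj]
        info = {"links": None}
    else:
        dist = np.sqrt(((roi.voxel_coords[tgt][:, None, :].astype(float)
                         - roi.voxel_coords[None, :, :].astype(float)) ** 2
                        ).sum(axis=2))
        n_partners = effect.n_shortcut_partners
        partners = []
        non_tgt = ~np.isin(np.arange(n), tgt)
        for k in range(len(tgt)):
            # distal = beyond the 75th distance percentile of non-target
            # voxels (with an absolute floor), so shortcuts scale with the
            # ROI's physical extent
            cut = max(min_shortcut_dist_vox,
                      float(np.quantile(dist[k][non_tgt], 0.75)))
            candidates = np.flatnonzero((dist[k] >= cut) & non_tgt)
            if len(candidates) < n_partners:
                candidates = np.flatnonzero(non_tgt)[
                    np.argsort(dist[k][non_tgt])[-max(n_partners, 1):]]
            if len(candidates) < n_partners:
                raise ValueError("ROI too small for the requested shortcut "
                                 "distance")
            partners.append(rng.choice(candidates, size=n_partners,
                                       replace=False))
        ei = np.repeat(tgt, n_partners)
        ej = np.concatenate(partners)
        info = {"links": list(zip(ei.tolist(), ej.tolist()))}
        # both link endpoints move toward each other: the coupling each side
        # gives up locally is halved, and the partners' share is scattered
        # thinly over the ROI, so the target keeps most of its local
        # architecture while acquiring distal voxels that resonate with it.
        mix_rows = np.unique(np.concatenate([ei, ej]))
        ref_map = {}
        for a, b in zip(ei, ej):
            ref_map.setdefault(int(b), []).append(int(a))
            ref_map.setdefault(int(a), []).append(int(b))
        ref = np.stack([weights[ref_map[int(v)]].mean(axis=0)
                        for v in mix_rows])
        tgt_mix = mix_rows

    if effect.kind == "local_coupling":
        tgt_mix = tgt

    r_ref = float(np.mean(cov0[ei, ej] / np.sqrt(var0[ei] * var0[ej])))
    power = np.sqrt((weights**2).sum(axis=1))

    def mixed(beta):
        w = weights.copy()
        rows = (1.0 - beta) * weights[tgt_mix] + beta * ref
        norms = np.linalg.norm(rows, axis=1)
        w[tgt_mix] = rows * (power[tgt_mix] / np.maximum(norms, 1e-300))[:, None]
        return w

    def gain(beta):
        w = mixed(beta)
        cov = w @ w.T
        var = np.diag(cov) + noise_var
        r = np.mean(cov[ei, ej] / np.sqrt(var[ei] * var[ej]))
        return r - r_ref - delta

    # gain(beta) can be non-monotonic (symmetric link mixing peaks where the
    # two endpoint profiles meet); solve on the rising branch and treat the
    # maximizer as the architecture's saturation point
    opt = optimize.minimize_scalar(lambda b: -gain(b), bounds=(0.0, 1.0),
                                   method="bounded")
    beta_max = float(opt.x)
    if gain(beta_max) < 0:
        if not saturate:
            raise ValueError(
                "coupling_delta unreachable: even full profile convergence "
                "cannot raise correlations that far")
        # the architecture bounds the achievable synchronization gain; a
        # study's per-subject effect saturates at that bound (weakly coupled
        # subjects express weaker effects)
        beta = beta_max
        info["saturated"] = True
    else:
        beta = optimize.brentq(gain, 0.0, beta_max, xtol=1e-12)
    info["beta"] = float(beta)
    info["realized_delta"] = float(gain(beta) + delta)
    return mixed(beta), info


# --------------------------------------------------------------------------
# nuisance machinery


def _smooth_walk(n, rng, smooth_sigma=6.0):
    w = np.cumsum(rng.standard_normal(n))
    w = gaussian_filter1d(w, smooth_sigma, mode="nearest")
    w -= w.mean()
    rms = np.sqrt(np.mean(w**2))
    return w / rms if rms > 0 else w


def make_nuisance(n_timepoints: int, tr: float, rng: np.random.Generator,
                  motion_rms: float = 0.2) -> NuisanceSet:
    """Synthetic nine-regressor nuisance set.

    Motion traces are smooth random walks scaled to a given rms (default
    0.2 mm / 0.2 deg, comfortably inside a 1 mm / 1 deg QC limit; raise
    ``motion_rms`` above 1 to exercise the exclusion rule).  WM/CSF are
    smooth unit-variance traces; the global trace is a slow drift plus a
    low-frequency physiological proxy.
    """
    motion = np.stack([_smooth_walk(n_timepoints, rng) * motion_rms
                       for _ in range(6)])
    wm = _smooth_walk(n_timepoints, rng, smooth_sigma=3.0)
    csf = _smooth_walk(n_timepoints, rng, smooth_sigma=3.0)
    t = np.arange(n_timepoints) * tr
    drift = 0.8 * (t - t.mean()) / (t.max() - t.min() + 1e-12)
    physio = 0.5 * np.sin(2 * np.pi * 0.005 * t + rng.uniform(0, 2 * np.pi))
    glob = drift + physio + 0.2 * _smooth_walk(n_timepoints, rng, smooth_sigma=8.0)
    return NuisanceSet(np.vstack([motion, wm, csf, glob]))


# --------------------------------------------------------------------------
# session / study simulation


def simulate_session(roi: RoiMask, effect: EffectSpec = EffectSpec(),
                     n_timepoints: int = 175, tr_seconds: float = 1.8,
                     noise_sd: float = 1.0, seed: int = 0, *,
                     architecture_seed: int | None = None,
                     signal_amplitude: float = 1.0,
                     length_scale_vox: float = 0.7,
                     center_spacing_vox: float = 1.7,
                     ar_phi: float = 0.3,
                     motion_rms: float = 0.2,
                     nuisance_gain: float = 1.0,
                     baseline_offset: float = 100.0,
                     effect_saturate: bool = True
                     ) -> tuple[BoldSeries, NuisanceSet]:
    """Simulate one resting-state acquisition for an ROI.

    Returns the raw BOLD series (including two initial dummy volumes with a
    magnetization transient, nuisance contamination and AR(1) noise) and the
    matching nine-regressor nuisance set.  Deterministic given ``seed``.

    The planted-effect strength is solved against the generator's covariance
    model evaluated with the *in-band* noise variance, i.e. the requested
    ``coupling_delta`` refers to correlations after band-pass filtering.
    """
    if n_timepoints < 50:
        raise ValueError("n_timepoints must be >= 50")
    # two streams: the *architecture* rng fixes the subject's stable
    # functional structure (community centres, mixing weights, effect links,
    # nuisance coupling weights), the *session* rng draws everything that
    # varies between repeated scans (latent phases, noise, nuisance traces).
    # A study passes the same architecture_seed for all sessions of one
    # subject so that before/after graphs differ only by noise and effect.
    rng_arch = np.random.default_rng(seed if architecture_seed is None
                                     else architecture_seed)
    rng = np.random.default_rng(seed)
    n = roi.n_voxels

    band_frac = _inband_noise_fraction(ar_phi, tr_seconds, 0.01, 0.09)
    noise_var_inband = noise_sd**2 / (1 - ar_phi**2) * band_frac
    # signal_amplitude is the in-band signal/noise sd ratio: the default
    # 0.8, with the 0.7-voxel community length scale, puts nearest-neighbour
    # correlations near 0.45, per-dataset T_max in the high 0.3s and mean
    # degree around 20 at the group threshold -- a sparse small-world regime
    signal_sd = signal_amplitude * np.sqrt(noise_var_inband)
    capacity = band_capacity(n_timepoints, tr_seconds)
    weights = _community_weights(roi, rng_arch, length_scale_vox,
                                 center_spacing_vox, signal_sd,
                                 max_centers=capacity)
    weights, _info = _apply_effect(roi, effect, weights, noise_var_inband,
                                   rng_arch, saturate=effect_saturate)

    latents = _band_limited_latents(weights.shape[1], n_timepoints,
                                    tr_seconds, rng)
    signal_part = weights @ latents.T                     # (N, T)
    noise_part = _ar1_noise((n, n_timepoints), ar_phi, noise_sd, rng)

    nuis = make_nuisance(n_timepoints, tr_seconds, rng, motion_rms=motion_rms)
    # per-voxel nuisance couplings: every voxel carries the global trace and a
    # random small dose of motion and tissue traces
    g_w = nuisance_gain * (0.5 + 0.2 * rng_arch.random(n))
    mot_w = nuisance_gain * 0.1 * rng_arch.standard_normal((n, 6))
    tis_w = nuisance_gain * 0.1 * rng_arch.standard_normal((n, 2))
    nuis_part = (np.outer(g_w, nuis.regressors[8])
                 + mot_w @ nuis.regressors[:6]
                 + tis_w @ nuis.regressors[6:8])

    transient = np.zeros(n_timepoints)
    transient[:4] = 3.0 * np.exp(-np.arange(4) / 0.8)     # T1 saturation decay
    data = baseline_offset + signal_part + nuis_part + noise_part + transient
    return BoldSeries(data=data, tr_seconds=tr_seconds, roi=roi), nuis


@dataclass
class SessionRecord:
    subject: int
    session: str
    time: str
    bold: BoldSeries
    nuisance: NuisanceSet
    effect: EffectSpec
    seed: int


@dataclass
class StudyData:
    """All simulated datasets of a study plus ground-truth labels."""

    design: StudyDesign
    roi: RoiMask
    records: list
    target_voxels: tuple
    subject_baseline: np.ndarray     # per-subject baseline coupling multiplier
    subject_effect: np.ndarray       # per-subject effect-size multiplier

    @property
    def n_datasets(self) -> int:
        return len(self.records)

    def get(self, subject: int, session: str, time: str) -> SessionRecord:
        for rec in self.records:
            if (rec.subject, rec.session, rec.time) == (subject, session, time):
                return rec
        raise KeyError((subject, session, time))

    def ground_truth(self) -> dict:
        return {
            "target_voxels": [int(v) for v in self.target_voxels],
            "subject_baseline": self.subject_baseline.tolist(),
            "subject_effect": self.subject_effect.tolist(),
            "effects": {f"{s}/{t}": self.design.effect_for(s, t).kind
                        for s in self.design.sessions for t in self.design.times},
        }


def simulate_study(design: StudyDesign, roi_params: dict | None = None,
                   session_params: dict | None = None,
                   subject_specific_rois: bool = False) -> StudyData:
    """Simulate every (subject, session, time) cell of a study design.

    One shared ROI geometry is used by default so that voxelwise group
    statistics have a common support (set ``subject_specific_rois`` to
    regenerate the mask per subject; group statistics then require identical
    masks, which ``make_roi`` guarantees only for the ``slab`` shape).
    Per-subject heterogeneity enters through a latent u_s that scales the
    community coupling (baseline multiplier ``exp(h * u_s)``) and, when
    ``baseline_effect_rho`` is set, correlates with the per-subject effect
    multiplier -- the substrate for baseline-dependence analyses.
    """
    roi_params = dict(roi_params or {})
    session_params = dict(session_params or {})
    roi_params.setdefault("n_voxels", 470)
    roi_params.setdefault("shape", "slab")
    roi_params.setdefault("seed", design.seed)

    ss = np.random.SeedSequence(design.seed)
    subj_seeds = ss.spawn(design.n_subjects)
    rng_study = np.random.default_rng(ss.spawn(1)[0])

    u = rng_study.standard_normal(design.n_subjects)
    v = rng_study.standard_normal(design.n_subjects)
    h = design.subject_heterogeneity
    baseline_mult = np.exp(h * u)
    rho = design.baseline_effect_rho
    e_h = design.effect_heterogeneity
    effect_mult = np.maximum(
        0.0, 1.0 + e_h * (rho * u + np.sqrt(max(0.0, 1 - rho**2)) * v))

    roi = make_roi(**roi_params)
    target = session_params.pop("target_voxels", None)
    if target is None:
        # fall back: compact central subregion of ~8.5% of the ROI
        target = select_subregion(roi, max(8, roi.n_voxels // 12),
                                  seed=design.seed)
    target = tuple(int(t) for t in target)

    records = []
    for s in range(design.n_subjects):
        cell_seeds = subj_seeds[s].spawn(len(design.sessions) * len(design.times) + 2)
        arch_seed = int(cell_seeds[-2].generate_state(1)[0] % 2**31)
        if subject_specific_rois:
            sroi_params = dict(roi_params)
            sroi_params["seed"] = int(cell_seeds[-1].generate_state(1)[0] % 2**31)
            sroi = make_roi(**sroi_params)
        else:
            sroi = roi
        k = 0
        for session in design.sessions:
            for time in design.times:
                eff = design.effect_for(session, time)
                eff = replace(eff, target_voxels=target,
                              baseline_scaling=float(effect_mult[s]))
                seed = int(cell_seeds[k].generate_state(1)[0] % 2**31)
                k += 1
                params = dict(session_params)
                params["signal_amplitude"] = (params.get("signal_amplitude", 1.0)
                                              * float(baseline_mult[s]))
                bold, nuis = simulate_session(sroi, eff, seed=seed,
                                              architecture_seed=arch_seed,
                                              effect_saturate=True,
                                              **params)
                records.append(SessionRecord(subject=s, session=session,
                                             time=time, bold=bold,
                                             nuisance=nuis, effect=eff,
                                             seed=seed))
    if design.n_datasets != len(records):   # pragma: no cover - sanity
        warnings.warn("design cell count mismatch")
    return StudyData(design=design, roi=roi, records=records,
                     target_voxels=target, subject_baseline=baseline_mult,
                     subject_effect=effect_mult)
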