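"""Synthetic phase-coupled EEG cohorts with known ground truth.

Each simulated subject is a network of Kuramoto-style phase oscillators,
one per electrode: channel i evolves as

    theta_i(t+1) = theta_i(t) + 2*pi*f_i/fs
                   + (gain/fs) * mean_{j in coupled(i)} K_ij sin(theta_j - theta_i)
                   + phase noise,

(the coupling pull is averaged over each channel's coupled neighbours, the
usual Kuramoto mean-field normalisation, so the effective per-step pull is
bounded by gain/fs regardless of how many pairs a channel participates in),
where K is the subject's symmetric coupling matrix in [0, 1] and f_i(t) is a
per-channel frequency drawn around a common base (alpha-band by default)
plus a slow Ornstein-Uhlenbeck wander. The wander matters: without it,
uncoupled channel pairs whose fixed frequencies happen to be close stay
spuriously phase-locked for the whole recording; with it, such chance
locking decoheres across windows while genuinely coupled pairs stay locked
because the coupling pull dominates the drift.
The observed signal is sin(theta) mixed spatially with a Gaussian kernel
over the montage coordinates (a volume-conduction surrogate) plus white
sensor noise. Phase-locking is exactly what this model controls: coupled
pairs lock (PLV near 1), uncoupled pairs drift apart (PLV near the finite-T
noise floor), so identification accuracy on these cohorts has a known,
tunable ground truth.

Defaults emulate the scale of 64-channel resting recordings sampled at
160 Hz with 10 +- 1 Hz base rhythms; they make no claim of biophysical
realism (no 1/f spectrum, no artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage, load_montage
from .windowing import Recording

__all__ = [
    "SubjectModel",
    "SyntheticCohort",
    "sample_subject",
    "simulate_recording",
    "simulate_cohort",
    "simulate_planted_cohort",
    "pure_region_channels",
    "save_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class SubjectModel:
    """Ground-truth generative parameters of one simulated subject."""

    coupling: np.ndarray  # (n, n) symmetric in [0,1], zero diagonal
    base_freq: float = 10.0  # Hz
    freq_jitter: float = 1.0  # Hz, fixed per-channel spread
    freq_drift_sd: float = 3.0  # Hz, sd of the slow OU frequency wander
    freq_drift_tau: float = 1.0  # s, OU time constant of the wander
    noise_sd: float = 0.5  # sensor noise, relative to signal sd
    phase_noise_sd: float = 0.1  # rad per step
    coupling_gain: float = 60.0  # rad/s at coupling == 1
    smoothing: float = 0.08  # Gaussian mixing width on the unit disc; 0 = off
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        K = np.asarray(self.coupling, dtype=float)
        object.__setattr__(self, "coupling", K)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("coupling must be square")
        if not np.allclose(K, K.T):
            raise ValueError("coupling must be symmetric")
        if np.any(np.diag(K) != 0):
            raise ValueError("coupling diagonal must be zero")
        if K.min() < 0 or K.max() > 1:
            raise ValueError("coupling entries must lie in [0, 1]")
        if self.noise_sd < 0 or self.phase_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.coupling.shape[0]


@dataclass
class SyntheticCohort:
    """A list of subjects with their simulated recordings."""

    subjects: list
    recordings: list  # flat list of Recording, labelled by subject_id
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list:
        return [s.subject_id for s in self.subjects]


def sample_subject(
    n_channels: int = 64,
    coupling_density: float = 0.02,
    coupling_strength: float = 1.0,
    seed: int = 0,
    channel_pool: "np.ndarray | None" = None,
    **model_kwargs,
) -> SubjectModel:
    """Draw a random symmetric coupling pattern for one subject.

    A fraction ``coupling_density`` of the n(n-1)/2 channel pairs is
    coupled at ``coupling_strength``; the rest are zero. ``channel_pool``
    optionally restricts coupled pairs to a subset of channels (used to
    plant region-specific signal). Distinct seeds give distinct patterns.
    """
    if not 0 < coupling_density <= 1:
        raise ValueError("coupling_density must be in (0, 1]")
    if not 0 <= coupling_strength <= 1:
        raise ValueError("coupling_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pool = np.arange(n_channels) if channel_pool is None else np.asarray(channel_pool, int)
    pairs = [(i, j) for a, i in enumerate(pool) for j in pool[a + 1 :]]
    n_total = n_channels * (n_channels - 1) // 2
    n_edges = int(round(coupling_density * n_total))
    n_edges = min(n_edges, len(pairs))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    K = np.zeros((n_channels, n_channels))
    for idx in chosen:
        i, j = pairs[idx]
        K[i, j] = K[j, i] = coupling_strength
    return SubjectModel(coupling=K, subject_id=f"S{seed}", **model_kwargs)


def _mixing_matrix(montage: Montage, width: float) -> np.ndarray:
    """Row-normalised Gaussian spatial mixing over montage coordinates."""
    pos = montage.positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    G = np.exp(-d2 / (2.0 * width**2))
    return G / G.sum(axis=1, keepdims=True)


def simulate_recording(
    subject: SubjectModel,
    duration_s: float = 60.0,
    fs: float = 160.0,
    seed: int = 0,
    montage: "Montage | None" = None,
) -> Recording:
    """Integrate the coupled-oscillator model and return the sensor signal.

    Deterministic for a fixed (subject, seed). ``montage`` supplies the
    electrode coordinates for the volume-conduction mixing; it defaults to
    the shipped 64-channel layout when the channel counts match, otherwise
    mixing is skipped.
    """
    if duration_s < 1.0:
        raise ValueError("duration must be at least 1 s")
    if fs < 32:
        raise ValueError("sampling rate must be at least 32 Hz")
    n = subject.n_channels
    T = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)

    freqs = subject.base_freq + subject.freq_jitter * rng.standard_normal(n)
    # mean-field normalisation: average the pull over each channel's neighbours
    n_neigh = np.maximum((subject.coupling > 0).sum(axis=1), 1)
    K = subject.coupling * (subject.coupling_gain / fs) / n_neigh[:, None]
    theta = rng.uniform(-np.pi, np.pi, size=n)
    noise = subject.phase_noise_sd * rng.standard_normal((T, n))
    # discretised OU frequency wander
    a = np.exp(-1.0 / (fs * subject.freq_drift_tau))
    b = subject.freq_drift_sd * np.sqrt(1.0 - a * a)
    wander_steps = rng.standard_normal((T, n))
    wander = np.zeros(n)

    phases = np.empty((n, T))
    coupled = np.any(K > 0)
    for t in range(T):
        phases[:, t] = theta
        if coupled:
            z = np.exp(1j * theta)
            pull = np.imag(np.conj(z) * (K @ z))  # mean_j K_ij sin(theta_j - theta_i)
        else:
            pull = 0.0
        wander = a * wander + b * wander_steps[t]
        theta = theta + 2.0 * np.pi * (freqs + wander) / fs + pull + noise[t]

    x = np.sin(phases)
    if subject.smoothing > 0:
        if montage is None and n == 64:
            montage = load_montage("physionet64")
        if montage is not None and montage.n_channels == n:
            x = _mixing_matrix(montage, subject.smoothing) @ x
    if subject.noise_sd > 0:
        x = x + subject.noise_sd * x.std() * rng.standard_normal(x.shape)
    return Recording(data=x, fs=fs, subject_id=subject.subject_id)


def simulate_cohort(
    n_subjects: int = 10,
    runs_per_subject: int = 3,
    duration_s: float = 60.0,
    fs: float = 160.0,
    n_channels: int = 64,
    coupling_density: float = 0.02,
    coupling_strength: float = 1.0,
    separation: float = 1.0,
    seed: int = 7,
    montage: "Montage | None" = None,
    **model_kwargs,
) -> SyntheticCohort:
    """Simulate a multi-subject cohort with subject-specific coupling.

    ``separation`` in [0, 1] controls how individual the coupling patterns
    are: each subject's coupled pairs are drawn as a mix of a cohort-shared
    backbone (fraction 1 - separation of the density budget) and a private
    pattern (fraction separation). At separation = 1 two subjects share
    coupled pairs only by chance, so their coupling-matrix correlation is
    bounded near the density itself.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not 0 <= separation <= 1:
        raise ValueError("separation must be in [0, 1]")
    root = np.random.SeedSequence(seed)
    ss_shared, ss_subj, ss_rec = root.spawn(3)

    shared_density = (1.0 - separation) * coupling_density
    private_density = separation * coupling_density
    shared = None
    if shared_density > 0:
        shared = sample_subject(
            n_channels,
            coupling_density=max(shared_density, 1e-9),
            coupling_strength=coupling_strength,
            seed=int(ss_shared.generate_state(1)[0] % (2**31)),
        ).coupling

    subjects = []
    subj_seeds = ss_subj.generate_state(n_subjects) % (2**31)
    for k in range(n_subjects):
        if private_density > 0:
            K = sample_subject(
                n_channels,
                coupling_density=private_density,
                coupling_strength=coupling_strength,
                seed=int(subj_seeds[k]),
                **{kw: v for kw, v in model_kwargs.items() if kw == "channel_pool"},
            ).coupling
        else:
            K = np.zeros((n_channels, n_channels))
        if shared is not None:
            K = np.maximum(K, shared)
        kwargs = {kw: v for kw, v in model_kwargs.items() if kw != "channel_pool"}
        subjects.append(SubjectModel(coupling=K, subject_id=f"S{k:02d}", **kwargs))

    recordings = []
    rec_seeds = ss_rec.generate_state(n_subjects * runs_per_subject) % (2**31)
    for k, subj in enumerate(subjects):
        for r in range(runs_per_subject):
            rec = simulate_recording(
                subj,
                duration_s=duration_s,
                fs=fs,
                seed=int(rec_seeds[k * runs_per_subject + r]),
                montage=montage,
            )
            rec.condition = f"run{r}"
            recordings.append(rec)

    params = dict(
        n_subjects=n_subjects,
        runs_per_subject=runs_per_subject,
        duration_s=duration_s,
        fs=fs,
        n_channels=n_channels,
        coupling_density=coupling_density,
        coupling_strength=coupling_strength,
        separation=separation,
        seed=seed,
    )
    return SyntheticCohort(subjects=subjects, recordings=recordings, seed=seed, params=params)


def pure_region_channels(montage: Montage, region: str) -> np.ndarray:
    """Channels belonging to ``region`` and to no other scalp region.

    Region masks overlap on boundary electrodes (FC, CP, PO, FT, TP); the
    pure set is what only this region's removal deletes, which is what a
    planted-signal ablation experiment needs.
    """
    from .montage import REGION_NAMES, region_mask

    own = region_mask(montage, region).channels
    others = set()
    for other in REGION_NAMES:
        if other != region:
            others |= region_mask(montage, other).channels
    return np.array(sorted(own - others), dtype=int)


def simulate_planted_cohort(
    region: str = "frontal",
    n_subjects: int = 6,
    runs_per_subject: int = 2,
    duration_s: float = 20.0,
    fs: float = 160.0,
    coupling_density: float = 0.005,
    seed: int = 1,
    montage: "Montage | None" = None,
) -> SyntheticCohort:
    """Cohort whose subject-specific coupling lives only in one scalp region.

    All coupled pairs are drawn among the region's *pure* channels (those no
    other region claims), so removing that region deletes the entire
    identifying signal while removing any other region leaves it intact —
    the ground truth for the region-removal ablation's directional check.
    The density is kept low (about 10 coupled pairs) so the planted pairs
    lock pairwise instead of fusing into one synchronised blob that would
    look identical across subjects.
    """
    montage = montage or load_montage("physionet64")
    pool = pure_region_channels(montage, region)
    cohort = simulate_cohort(
        n_subjects=n_subjects,
        runs_per_subject=runs_per_subject,
        duration_s=duration_s,
        fs=fs,
        n_channels=montage.n_channels,
        coupling_density=coupling_density,
        seed=seed,
        montage=montage,
        channel_pool=pool,
    )
    cohort.params["planted_region"] = region
    return cohort


def save_cohort(path, cohort: SyntheticCohort) -> None:
    """Persist a cohort (ground truth + recordings) to an HDF5 container."""
    import h5py
    import json

    with h5py.File(path, "w") as f:
        f.attrs["seed"] = cohort.seed
        f.attrs["params"] = json.dumps(cohort.params)
        gsub = f.create_group("subjects")
        for s in cohort.subjects:
            g = gsub.create_group(s.subject_id)
            g.create_dataset("coupling", data=s.coupling)
            g.attrs["base_freq"] = s.base_freq
            g.attrs["noise_sd"] = s.noise_sd
        grec = f.create_group("recordings")
        for i, r in enumerate(cohort.recordings):
            g = grec.create_group(f"r{i:04d}")
            g.create_dataset("data", data=r.data)
            g.attrs["fs"] = r.fs
            g.attrs["subject_id"] = r.subject_id
            g.attrs["condition"] = r.condition


def load_cohort(path) -> SyntheticCohort:
    """Load a cohort saved by :func:`save_cohort`."""
    import h5py
    import json

    with h5py.File(path, "r") as f:
        params = json.loads(f.attrs["params"])
        subjects = []
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            subjects.append(
                SubjectModel(
                    coupling=g["coupling"][()],
                    base_freq=float(g.attrs["base_freq"]),
                    noise_sd=float(g.attrs["noise_sd"]),
                    subject_id=sid,
                )
            )
        recordings = []
        for rid in sorted(f["recordings"]):
            g = f["recordings"][rid]
            recordings.append(
                Recording(
                    data=g["data"][()],
                    fs=float(g.attrs["fs"]),
                    subject_id=str(g.attrs["subject_id"]),
                    condition=str(g.attrs["condition"]),
                )
            )
        return SyntheticCohort(
            subjects=subjects, recordings=recordings, seed=int(f.attrs["seed"]), params=params
        )
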