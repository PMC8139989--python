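"""Synthetic four-contact cuff recordings with known afferent/efferent ground truth.

The generator emulates an anesthetized-rodent preparation: a nerve cuff with
four contacts spaced 2.5 mm apart (12-mm cuff) records action potentials
propagating in one of two directions. An afferent spike passes the contacts
in order 1→4, an efferent spike in order 4→1, so the per-contact arrival
delays of the efferent rendering are the reverse of the afferent ones.
Because the tetrapolar combination weights (-1/2, 3/2, -3/2, 1/2) are
antisymmetric under contact reversal, the efferent tetrapolar waveform is the
exact negative of the afferent one — the physical basis of direction
classification from a single cuff.

The scenario model follows an upper-airway obstruction protocol: a baseline
period, a series of 15-s obstructions separated by fixed gaps, and a post
period. Afferent firing (lung stretch receptors) is gated by a raised-cosine
respiratory rhythm and multiplied by a suppression factor during
obstructions; efferent firing is tonic. Transection conditions gate which
classes fire at all: intact = both, proximal transection = afferent only,
distal transection = efferent only, complete transection = noise only.

Noise is additive white Gaussian per contact, calibrated so that the
peak-to-peak SNR (20*log10[Vpp(signal)/Vpp(noise)], both measured at the
tetrapolar output, noise Vpp as the mean peak-to-peak over 1-ms windows)
matches a target in dB. ECG and EMG artifacts couple into the contacts with
a common + linear-gradient + small random-asymmetry weighting: the gradient
part cancels in the tetrapolar output (as it should in an ideal cuff) while
the asymmetry part leaves the realistic residual that motivates artifact
thresholding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .construct import TETRAPOLAR_COEFFS, ContactTraces

logger = logging.getLogger(__name__)

DIRECTIONS = ("afferent", "efferent")
CONDITIONS = ("intact", "proximal_transection", "distal_transection", "complete_transection")

#: Direction classes that fire under each transection paradigm.
CONDITION_CLASSES = {
    "intact": ("afferent", "efferent"),
    "proximal_transection": ("afferent",),
    "distal_transection": ("efferent",),
    "complete_transection": (),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CuffGeometry:
    """Longitudinal contact layout of the recording cuff."""

    contact_positions_mm: tuple[float, float, float, float] = (0.0, 2.5, 5.0, 7.5)
    cuff_length_mm: float = 12.0
    sampling_rate: float = 40_000.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.contact_positions_mm, dtype=float)
        if pos.size != 4:
            raise ValueError("exactly 4 contacts are required")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("contact positions must be strictly increasing")
        if not self.sampling_rate > 2 * 10_000:
            raise ValueError("sampling_rate must exceed twice the 10-kHz band edge")
        self.contact_positions_mm = tuple(pos)


@dataclass
class APTemplate:
    """Unit-peak biphasic action-potential waveform (µV after scaling)."""

    waveform: np.ndarray
    peak_amplitude_uv: float = 8.0
    polarity: int = 1

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.size == 0 or self.waveform.size > 41:
            raise ValueError("template duration must be 1..41 samples")
        m = np.max(np.abs(self.waveform))
        if not np.isclose(m, 1.0):
            raise ValueError("waveform must be unit-peak")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.peak_amplitude_uv <= 0:
            raise ValueError("peak_amplitude_uv must be positive")

    @classmethod
    def biphasic(
        cls,
        sampling_rate: float = 40_000.0,
        duration_ms: float = 0.8,
        peak_amplitude_uv: float = 8.0,
        polarity: int = 1,
        neg_fraction: float = 0.45,
    ) -> "APTemplate":
        """Positive lobe followed by a smaller negative lobe.

        The asymmetric lobes (second lobe ``neg_fraction`` of the first)
        follow the common extracellular convention of a dominant initial
        phase; total duration defaults to 0.8 ms.
        """
        n = int(round(duration_ms * 1e-3 * sampling_rate))
        n_pos = max(int(round(0.4 * n)), 2)
        n_neg = max(n - n_pos, 2)
        pos = np.sin(np.linspace(0.0, np.pi, n_pos, endpoint=False))
        neg = -neg_fraction * np.sin(np.linspace(0.0, np.pi, n_neg))
        w = np.concatenate([pos, neg])
        w /= np.max(np.abs(w))
        return cls(waveform=w, peak_amplitude_uv=peak_amplitude_uv, polarity=polarity)

    @property
    def samples_uv(self) -> np.ndarray:
        return self.waveform * self.peak_amplitude_uv * self.polarity

    @property
    def vpp_uv(self) -> float:
        s = self.samples_uv
        return float(s.max() - s.min())


@dataclass
class FiringSchedule:
    """Spike times with per-spike direction labels and amplitudes."""

    spike_times: np.ndarray
    directions: np.ndarray
    amplitudes_uv: np.ndarray | None = None
    respiratory_rate: float = 1.5
    base_rates: dict[str, float] = field(default_factory=lambda: {"afferent": 300.0, "efferent": 200.0})
    obstruction_suppression: float = 0.05

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.directions = np.asarray(self.directions, dtype=object)
        if self.spike_times.shape != self.directions.shape:
            raise ValueError("spike_times and directions must align")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be sorted")
        if any(d not in DIRECTIONS for d in self.directions):
            raise ValueError("directions must be 'afferent' or 'efferent'")
        if any(r < 0 for r in self.base_rates.values()):
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.obstruction_suppression <= 1.0:
            raise ValueError("obstruction_suppression must lie in [0, 1]")
        if self.amplitudes_uv is not None:
            self.amplitudes_uv = np.asarray(self.amplitudes_uv, dtype=float)
            if self.amplitudes_uv.shape != self.spike_times.shape:
                raise ValueError("amplitudes_uv must align with spike_times")

    def __len__(self) -> int:
        return self.spike_times.size


@dataclass
class Protocol:
    """Baseline / repeated-obstruction / post timing of one run."""

    baseline_s: float = 60.0
    n_obstructions: int = 5
    obstruction_s: float = 15.0
    gap_s: float = 60.0
    post_s: float = 60.0

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.obstruction_s, self.post_s) <= 0:
            raise ValueError("protocol durations must be positive")
        if self.n_obstructions < 1:
            raise ValueError("need at least one obstruction")
        if self.n_obstructions > 1 and self.gap_s <= 0:
            raise ValueError("gap between obstructions must be positive")

    def obstruction_intervals(self) -> list[tuple[float, float]]:
        out = []
        t = self.baseline_s
        for _ in range(self.n_obstructions):
            out.append((t, t + self.obstruction_s))
            t += self.obstruction_s + self.gap_s
        return out

    @property
    def total_s(self) -> float:
        n = self.n_obstructions
        return self.baseline_s + n * self.obstruction_s + (n - 1) * self.gap_s + self.post_s


@dataclass
class ScenarioConfig:
    """Full description of one simulated experiment."""

    condition: str = "intact"
    protocol: Protocol = field(default_factory=Protocol)
    geometry: CuffGeometry = field(default_factory=CuffGeometry)
    conduction_velocity: float = 25.0  # m/s; unstated in vivo, exposed here
    target_snr_db: float = 6.05
    peak_amplitude_uv: float = 8.0
    amplitude_jitter: float = 0.2
    afferent_rate: float = 300.0
    efferent_rate: float = 200.0
    respiratory_rate: float = 1.5
    obstruction_suppression: float = 0.05
    # artifact coupling into the cuff contacts
    ecg_rate_bpm: float = 360.0
    ecg_artifact_uv: float = 150.0
    ecg_artifact_gradient: float = 0.4
    contact_asymmetry: float = 0.02
    emg_artifact_uv: float = 10.0
    emg_burst_s: float = 0.15
    movement_artifact_uv: float = 2000.0
    movement_rate_hz: float = 0.1
    movement_width_s: float = 0.004
    # physiological channels
    physio_fs: float = 1000.0
    bp_baseline_mmhg: float = 100.0
    bp_effect: float = 0.20
    ggemg_effect: float = 1.38
    hr_effect: float = 0.05
    ggemg_burst_amplitude_mv: float = 2.5
    ggemg_burst_s: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.conduction_velocity <= 0:
            raise ValueError("conduction_velocity must be positive")
        if not 0.0 <= self.obstruction_suppression <= 1.0:
            raise ValueError("obstruction_suppression must lie in [0, 1]")
        if min(self.afferent_rate, self.efferent_rate) < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class Channel:
    """A single-channel physiological time series."""

    data: np.ndarray
    sampling_rate: float
    units: str
    name: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)


@dataclass
class GroundTruthManifest:
    """The simulator's record of everything needed for parameter recovery."""

    condition: str
    spike_times: np.ndarray
    directions: np.ndarray
    amplitudes_uv: np.ndarray
    obstruction_intervals: list[tuple[float, float]]
    true_snr_db: float
    base_rates: dict[str, float]
    respiratory_rate: float
    obstruction_suppression: float
    sampling_rate: float
    duration_s: float
    seed: int

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.directions = np.asarray(self.directions, dtype=object)
        self.amplitudes_uv = np.asarray(self.amplitudes_uv, dtype=float)
        if self.spike_times.size and (
            self.spike_times.min() < 0 or self.spike_times.max() > self.duration_s
        ):
            raise ValueError("manifest spike times fall outside the recording span")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def count(self, direction: str | None = None, interval: tuple[float, float] | None = None) -> int:
        sel = np.ones(self.spike_times.shape, dtype=bool)
        if direction is not None:
            sel &= self.directions == direction
        if interval is not None:
            sel &= (self.spike_times >= interval[0]) & (self.spike_times < interval[1])
        return int(sel.sum())

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "spike_times": self.spike_times.tolist(),
            "directions": list(self.directions),
            "amplitudes_uv": self.amplitudes_uv.tolist(),
            "obstruction_intervals": [list(iv) for iv in self.obstruction_intervals],
            "true_snr_db": self.true_snr_db,
            "base_rates": self.base_rates,
            "respiratory_rate": self.respiratory_rate,
            "obstruction_suppression": self.obstruction_suppression,
            "sampling_rate": self.sampling_rate,
            "duration_s": self.duration_s,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        d = dict(d)
        d["obstruction_intervals"] = [tuple(iv) for iv in d["obstruction_intervals"]]
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SyntheticRecording:
    contacts: ContactTraces
    ecg: Channel
    bp: Channel
    ggemg: Channel
    manifest: GroundTruthManifest


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def contact_delays(geometry: CuffGeometry, velocity: float, direction: str) -> np.ndarray:
    """Arrival delays (samples, possibly fractional) at the four contacts.

    Afferent propagation passes the contacts in position order; efferent
    propagation reverses the delay vector. ``velocity=inf`` gives all-zero
    delays (a far-field common-mode event).
    """
    if not velocity > 0:
        raise ValueError("velocity must be positive")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    pos = np.asarray(geometry.contact_positions_mm, dtype=float)
    delays = (pos - pos[0]) * 1e-3 / velocity * geometry.sampling_rate
    if direction == "efferent":
        delays = delays[::-1].copy()
    return delays


def render_contact_voltages(
    schedule: FiringSchedule,
    template: APTemplate,
    geometry: CuffGeometry,
    velocity: float,
    n_samples: int | None = None,
) -> ContactTraces:
    """Superpose the template at each spike's per-contact arrival times.

    Spikes whose waveform would extend past the trace bounds contribute only
    their in-bounds part (counted and logged). Output is linear in template
    amplitude.
    """
    fs = geometry.sampling_rate
    if n_samples is None:
        horizon = schedule.spike_times.max() + 2e-3 if len(schedule) else 1e-2
        n_samples = int(np.ceil(horizon * fs))
    traces = np.zeros((4, n_samples))
    delays = {d: contact_delays(geometry, velocity, d) for d in DIRECTIONS}
    w = template.waveform * template.polarity
    nw = w.size
    amps = (
        schedule.amplitudes_uv
        if schedule.amplitudes_uv is not None
        else np.full(len(schedule), template.peak_amplitude_uv)
    )
    n_clipped = 0
    for t, direction, amp in zip(schedule.spike_times, schedule.directions, amps):
        for c in range(4):
            start = int(round(t * fs + delays[direction][c]))
            lo, hi = max(start, 0), min(start + nw, n_samples)
            if lo >= hi:
                n_clipped += 1
                continue
            if hi - lo < nw:
                n_clipped += 1
            traces[c, lo:hi] += amp * w[lo - start : hi - start]
    if n_clipped:
        logger.warning("clipped %d spike renderings at trace bounds", n_clipped)
    return ContactTraces(*traces, sampling_rate=fs)


def noise_vpp_estimate(x: np.ndarray, sampling_rate: float, window_s: float = 1e-3) -> float:
    """Mean peak-to-peak over consecutive 1-ms windows — the Vpp estimator
    used for SNR calibration."""
    win = max(int(round(window_s * sampling_rate)), 2)
    n = (len(x) // win) * win
    if n == 0:
        raise ValueError("trace shorter than one estimation window")
    blocks = np.asarray(x[:n]).reshape(-1, win)
    return float(np.mean(blocks.max(axis=1) - blocks.min(axis=1)))


def tetra_spike_vpp(
    template: APTemplate, geometry: CuffGeometry, velocity: float, direction: str = "afferent"
) -> float:
    """Peak-to-peak amplitude of a single clean spike at the tetrapolar output."""
    pad = int(np.ceil(max(contact_delays(geometry, velocity, "afferent")))) + template.waveform.size + 8
    sched = FiringSchedule(
        spike_times=np.array([pad / geometry.sampling_rate]),
        directions=np.array([direction], dtype=object),
        amplitudes_uv=np.array([template.peak_amplitude_uv]),
    )
    contacts = render_contact_voltages(sched, template, geometry, velocity, n_samples=3 * pad)
    tetra = TETRAPOLAR_COEFFS @ contacts.stack()
    return float(tetra.max() - tetra.min())


def add_calibrated_noise(
    traces: ContactTraces,
    target_snr_db: float,
    template_vpp_uv: float,
    seed: int | np.random.Generator = 0,
) -> tuple[ContactTraces, float]:
    """Add white Gaussian noise per contact, calibrated at the tetrapolar output.

    The per-contact noise is scaled so that the mean 1-ms-window peak-to-peak
    of the *tetrapolar* noise yields ``20*log10(template_vpp/noise_vpp) ==
    target_snr_db``. Returns the noisy traces and the achieved SNR.
    ``target_snr_db=inf`` returns the traces unchanged.
    """
    if not np.isfinite(target_snr_db):
        if target_snr_db > 0:
            return traces, float("inf")
        raise ValueError("target_snr_db must be finite or +inf")
    if template_vpp_uv <= 0:
        raise ValueError("template_vpp_uv must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = rng.standard_normal((4, traces.n_samples))
    tetra_noise = TETRAPOLAR_COEFFS @ raw
    target_noise_vpp = template_vpp_uv / 10.0 ** (target_snr_db / 20.0)
    scale = target_noise_vpp / noise_vpp_estimate(tetra_noise, traces.sampling_rate)
    noisy = traces.stack() + scale * raw
    achieved = 20.0 * np.log10(
        template_vpp_uv / noise_vpp_estimate(scale * tetra_noise, traces.sampling_rate)
    )
    return ContactTraces(*noisy, sampling_rate=traces.sampling_rate), float(achieved)


def _in_intervals(t: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(t.shape, dtype=bool)
    for lo, hi in intervals:
        mask |= (t >= lo) & (t < hi)
    return mask


def sample_schedule(config: ScenarioConfig, rng: np.random.Generator) -> FiringSchedule:
    """Draw the inhomogeneous-Poisson firing schedule for one scenario.

    Afferent rate: ``base * (1 - cos(2*pi*f_resp*t))`` (raised-cosine
    respiratory gating, time-average equal to the base rate), multiplied by
    the suppression factor inside obstruction epochs. Efferent rate: tonic.
    Spike collisions are allowed (pure superposition, no refractoriness).
    """
    protocol = config.protocol
    total = protocol.total_s
    obstructions = protocol.obstruction_intervals()
    times, dirs = [], []
    active = CONDITION_CLASSES[config.condition]

    if "afferent" in active and config.afferent_rate > 0:
        lam_max = 2.0 * config.afferent_rate
        n_cand = rng.poisson(lam_max * total)
        cand = np.sort(rng.uniform(0.0, total, n_cand))
        lam = config.afferent_rate * (1.0 - np.cos(2.0 * np.pi * config.respiratory_rate * cand))
        lam[_in_intervals(cand, obstructions)] *= config.obstruction_suppression
        keep = rng.uniform(0.0, lam_max, n_cand) < lam
        times.append(cand[keep])
        dirs.append(np.full(keep.sum(), "afferent", dtype=object))

    if "efferent" in active and config.efferent_rate > 0:
        n_eff = rng.poisson(config.efferent_rate * total)
        times.append(np.sort(rng.uniform(0.0, total, n_eff)))
        dirs.append(np.full(n_eff, "efferent", dtype=object))

    if times:
        t = np.concatenate(times)
        d = np.concatenate(dirs)
        order = np.argsort(t, kind="stable")
        t, d = t[order], d[order]
    else:
        t = np.empty(0)
        d = np.empty(0, dtype=object)
    amps = config.peak_amplitude_uv * (
        1.0 + config.amplitude_jitter * rng.uniform(-1.0, 1.0, t.size)
    )
    return FiringSchedule(
        spike_times=t,
        directions=d,
        amplitudes_uv=amps,
        respiratory_rate=config.respiratory_rate,
        base_rates={"afferent": config.afferent_rate, "efferent": config.efferent_rate},
        obstruction_suppression=config.obstruction_suppression,
    )


def _pulse_train(
    n: int, fs: float, centers_s: np.ndarray, width_s: float, amplitudes: np.ndarray
) -> np.ndarray:
    """Sum of triangular pulses; used for ECG R-waves and burst envelopes."""
    out = np.zeros(n)
    half = max(int(round(width_s * fs / 2)), 1)
    shape = 1.0 - np.abs(np.arange(-half, half + 1)) / half
    for c, a in zip(centers_s, amplitudes):
        k = int(round(c * fs))
        lo, hi = max(k - half, 0), min(k + half + 1, n)
        if lo >= hi:
            continue
        out[lo:hi] += a * shape[lo - (k - half) : hi - (k - half)]
    return out


def _artifact_weights(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-contact coupling of far-field artifacts.

    Common + linear-gradient terms cancel exactly in the tetrapolar output;
    the small random per-contact asymmetry (impedance mismatch) leaves the
    residual seen in practice.
    """
    u = np.array([-0.5, -1.0 / 6.0, 1.0 / 6.0, 0.5])
    return 1.0 + config.ecg_artifact_gradient * u + config.contact_asymmetry * rng.standard_normal(4)


def simulate_physio(
    config: ScenarioConfig, rng: np.random.Generator | int | None = None
) -> tuple[Channel, Channel, Channel]:
    """ECG, blood-pressure and genioglossus-EMG channels for one scenario.

    ECG: R-peak train at the configured heart rate (raised by ``hr_effect``
    during obstructions). BP: baseline mean stepped up by ``bp_effect``
    during obstructions, with a pulse ripple and measurement noise. GGEMG:
    one noise burst per respiratory cycle whose amplitude (hence per-burst
    area) rises by ``ggemg_effect`` during obstructions.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed + 101 if rng is None else rng)
    fs = config.physio_fs
    protocol = config.protocol
    total = protocol.total_s
    obstructions = protocol.obstruction_intervals()
    n = int(round(total * fs))
    t = np.arange(n) / fs
    obst_mask = _in_intervals(t, obstructions)

    # --- ECG ---
    r_times = []
    tt = 0.0
    while tt < total:
        r_times.append(tt)
        hr = config.ecg_rate_bpm * (1.0 + (config.hr_effect if _in_intervals(np.array([tt]), obstructions)[0] else 0.0))
        tt += 60.0 / hr
    r_times = np.asarray(r_times)
    ecg = _pulse_train(n, fs, r_times, 0.02, np.full(r_times.size, 1.0))
    ecg += 0.02 * rng.standard_normal(n)

    # --- BP ---
    bp = config.bp_baseline_mmhg * (1.0 + config.bp_effect * obst_mask.astype(float))
    bp += 2.0 * np.sin(2.0 * np.pi * (config.ecg_rate_bpm / 60.0) * t)
    bp += 0.3 * rng.standard_normal(n)

    # --- GGEMG ---
    burst_times = np.arange(0.25 / config.respiratory_rate, total, 1.0 / config.respiratory_rate)
    burst_amp = config.ggemg_burst_amplitude_mv * (
        1.0 + config.ggemg_effect * _in_intervals(burst_times, obstructions).astype(float)
    )
    envelope = _pulse_train(n, fs, burst_times, config.ggemg_burst_s, burst_amp)
    ggemg = envelope * rng.standard_normal(n) * np.sqrt(np.pi / 2.0)
    ggemg += 0.01 * rng.standard_normal(n)

    return (
        Channel(ecg, fs, "mV", "ECG"),
        Channel(bp, fs, "mmHg", "BP"),
        Channel(ggemg, fs, "mV", "GGEMG"),
    )


def simulate_recording(config: ScenarioConfig) -> SyntheticRecording:
    """Full synthetic experiment: neural contacts + physiology + manifest."""
    rng = np.random.default_rng(config.seed)
    geometry = config.geometry
    fs = geometry.sampling_rate
    protocol = config.protocol
    total = protocol.total_s
    n = int(round(total * fs))

    template = APTemplate.biphasic(fs, peak_amplitude_uv=config.peak_amplitude_uv)
    schedule = sample_schedule(config, rng)
    contacts = render_contact_voltages(schedule, template, geometry, config.conduction_velocity, n)
    traces = contacts.stack()

    # far-field artifacts (µV) with realistic imperfect tetrapolar rejection
    weights = _artifact_weights(config, rng)
    t_axis = np.arange(n) / fs
    if config.ecg_artifact_uv > 0:
        r_times = np.arange(0.0, total, 60.0 / config.ecg_rate_bpm)
        pulse = _pulse_train(n, fs, r_times, 0.006, np.full(r_times.size, config.ecg_artifact_uv))
        traces += weights[:, None] * pulse[None, :]
    if config.emg_artifact_uv > 0:
        burst_times = np.arange(0.25 / config.respiratory_rate, total, 1.0 / config.respiratory_rate)
        env = _pulse_train(n, fs, burst_times, config.emg_burst_s, np.full(burst_times.size, 1.0))
        emg = config.emg_artifact_uv * env * rng.standard_normal(n)
        traces += weights[:, None] * emg[None, :]
    if config.movement_artifact_uv > 0 and config.movement_rate_hz > 0:
        # sparse large events (movement, catheter flush) that exceed the
        # 700-µV blanking limit on the bipolar derivations
        n_mov = rng.poisson(config.movement_rate_hz * total)
        mov_times = np.sort(rng.uniform(0.0, total, n_mov))
        mov = _pulse_train(
            n, fs, mov_times, config.movement_width_s,
            np.full(mov_times.size, config.movement_artifact_uv),
        )
        traces += weights[:, None] * mov[None, :]

    contacts = ContactTraces(*traces, sampling_rate=fs)
    vpp = tetra_spike_vpp(template, geometry, config.conduction_velocity)
    contacts, achieved_snr = add_calibrated_noise(contacts, config.target_snr_db, vpp, rng)

    ecg, bp, ggemg = simulate_physio(config, rng)
    manifest = GroundTruthManifest(
        condition=config.condition,
        spike_times=schedule.spike_times,
        directions=schedule.directions,
        amplitudes_uv=schedule.amplitudes_uv,
        obstruction_intervals=protocol.obstruction_intervals(),
        true_snr_db=achieved_snr,
        base_rates=dict(schedule.base_rates),
        respiratory_rate=config.respiratory_rate,
        obstruction_suppression=config.obstruction_suppression,
        sampling_rate=fs,
        duration_s=total,
        seed=config.seed,
    )
    return SyntheticRecording(contacts, ecg, bp, ggemg, manifest)


def synthesize_labeled_windows(
    n_per_class: int,
    snr_db: float,
    seed: int = 0,
    geometry: CuffGeometry | None = None,
    template: APTemplate | None = None,
    velocity: float = 25.0,
    amplitude_jitter: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Labelled 41-sample tetrapolar spike windows for classifier studies.

    Renders one afferent and one efferent clean contact-level spike, adds
    per-contact calibrated Gaussian noise, band-passes the tetrapolar trace
    and extracts the 41-sample window centred on the dominant extremum near
    the true spike time — the same physics and processing as the full
    pipeline, vectorised for corpus-scale generation.

    Returns ``(windows, labels, sampling_rate)`` with label 0 = efferent,
    1 = afferent (the two-class convention used throughout).
    """
    from ._filters import apply_zero_phase, design_bandpass  # local to avoid cycle at import

    geometry = geometry or CuffGeometry()
    template = template or APTemplate.biphasic(geometry.sampling_rate)
    fs = geometry.sampling_rate
    rng = np.random.default_rng(seed)
    L = 161
    center = L // 2

    clean = {}
    for direction in DIRECTIONS:
        sched = FiringSchedule(
            spike_times=np.array([(center - template.waveform.size // 2) / fs]),
            directions=np.array([direction], dtype=object),
            amplitudes_uv=np.array([template.peak_amplitude_uv]),
        )
        c = render_contact_voltages(sched, template, geometry, velocity, n_samples=L)
        clean[direction] = TETRAPOLAR_COEFFS @ c.stack()

    vpp = tetra_spike_vpp(template, geometry, velocity)
    target_noise_vpp = vpp / 10.0 ** (snr_db / 20.0)
    calib = np.random.default_rng(seed + 1).standard_normal((4, 400_000))
    sigma = target_noise_vpp / noise_vpp_estimate(TETRAPOLAR_COEFFS @ calib, fs)

    n_total = 2 * n_per_class
    labels = np.concatenate([np.ones(n_per_class, dtype=int), np.zeros(n_per_class, dtype=int)])
    base = np.vstack(
        [np.tile(clean["afferent"], (n_per_class, 1)), np.tile(clean["efferent"], (n_per_class, 1))]
    )
    jitter = 1.0 + amplitude_jitter * rng.uniform(-1.0, 1.0, n_total)
    noise = sigma * np.einsum("c,ncl->nl", TETRAPOLAR_COEFFS, rng.standard_normal((n_total, 4, L)))
    tetra = base * jitter[:, None] + noise
    tetra = apply_zero_phase(design_bandpass(fs), tetra, axis=-1)

    lo, hi = center - 20, center + 21
    local = np.argmax(np.abs(tetra[:, lo:hi]), axis=1) + lo
    idx = local[:, None] + np.arange(-20, 21)[None, :]
    windows = np.take_along_axis(tetra, idx, axis=1)

    perm = rng.permutation(n_total)
    return windows[perm], labels[perm], fs
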