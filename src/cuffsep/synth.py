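"""Synthetic multichannel nerve-cuff recordings.

Forward model: each fascicle carries an independent band-limited Gaussian
source process whose amplitude is gated by the stimulation protocol; every
cuff contact picks the sources up through a distance-dependent weight, and
independent white noise is added per contact.  The model is a deliberately
simple stand-in for volume conduction — its job is to give the downstream
pipeline the spatial/statistical structure it is designed to exploit
(amplitude coding of stimulus intensity, contact-to-contact amplitude
ratios that differ only when fascicles are spatially separated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "ContactSpec",
    "CuffLayout",
    "FascicleSpec",
    "NerveSiteModel",
    "StimulusClass",
    "StimulationProtocol",
    "RawRecording",
    "build_cuff_layout",
    "compute_pickup_weights",
    "generate_protocol",
    "synthesize_recording",
    "synthesize_fsr_trace",
    "make_site_model",
    "proprioception_classes",
    "ten_class_set",
]

#: number of angular quadrature points used to model a full-ring contact
RING_QUADRATURE_POINTS = 36

#: default band of the fascicular source processes (Hz); brackets the
#: 800-2200 Hz analysis band so the bandpass filter removes some but not
#: all source power
SOURCE_BAND = (300.0, 3000.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactSpec:
    """One electrode contact on a cylindrical cuff."""

    contact_id: int
    kind: str  # "point" or "ring"
    axial_pos: float  # mm along the cuff axis
    angular_pos: float = 0.0  # degrees in [0, 360); only meaningful for points

    def __post_init__(self):
        if self.kind not in ("point", "ring"):
            raise ValueError(f"unknown contact kind {self.kind!r}")


@dataclass(frozen=True)
class CuffLayout:
    """Positions and types of the contacts of one cuff."""

    name: str
    cuff_length: float  # mm
    inner_diameter: float  # mm
    contacts: tuple[ContactSpec, ...]

    def __post_init__(self):
        ids = [c.contact_id for c in self.contacts]
        if len(set(ids)) != len(ids):
            raise ValueError("contact_ids must be unique within a layout")
        for c in self.contacts:
            if not (0.0 <= c.axial_pos <= self.cuff_length):
                raise ValueError(
                    f"contact {c.contact_id}: axial_pos {c.axial_pos} outside "
                    f"[0, {self.cuff_length}]"
                )

    @property
    def n_channels(self) -> int:
        return len(self.contacts)


@dataclass(frozen=True)
class FascicleSpec:
    """A fascicle in the nerve cross-section (origin = nerve axis)."""

    name: str
    center: tuple[float, float]  # (x, y) mm
    radius: float  # mm


@dataclass
class NerveSiteModel:
    """Fascicle layout plus class-by-fascicle activation gains at one site.

    ``gain_matrix`` has shape (n_fascicles, n_classes); entry [f, c] is the
    extra source amplitude of fascicle f while a class-c stimulus is ON.
    ``baseline_gain`` is the resting amplitude of every fascicle.
    ``pickup_d0`` (mm) and ``pickup_gamma`` parameterise the contact pickup
    weight (d0 / (d0 + d)) ** gamma.
    """

    site: str  # "distal" or "proximal"
    fascicles: list[FascicleSpec]
    gain_matrix: np.ndarray
    baseline_gain: float = 0.1
    pickup_d0: float = 0.1
    pickup_gamma: float = 2.0
    nerve_radius: float = 0.5

    def __post_init__(self):
        self.gain_matrix = np.asarray(self.gain_matrix, dtype=float)
        if self.gain_matrix.ndim != 2:
            raise ValueError("gain_matrix must be 2-D (fascicles x classes)")
        if self.gain_matrix.shape[0] != len(self.fascicles):
            raise ValueError(
                f"gain_matrix has {self.gain_matrix.shape[0]} rows but the "
                f"model has {len(self.fascicles)} fascicles"
            )
        if np.any(self.gain_matrix < 0):
            raise ValueError("activation gains must be nonnegative")
        if self.baseline_gain < 0:
            raise ValueError("baseline_gain must be nonnegative")
        for f in self.fascicles:
            if np.hypot(*f.center) + f.radius > self.nerve_radius + 1e-9:
                raise ValueError(
                    f"fascicle {f.name!r} does not fit inside the nerve "
                    f"cross-section (radius {self.nerve_radius} mm)"
                )


@dataclass(frozen=True)
class StimulusClass:
    """One stimulation class (label, modality and epoch timing)."""

    class_id: int
    label: str
    modality: str  # "proprioception" | "nociception" | "touch"
    on_duration: float  # s
    off_duration: float  # s

    def __post_init__(self):
        if self.on_duration <= 0 or self.off_duration <= 0:
            raise ValueError("stimulus ON/OFF durations must be positive")
        if self.modality not in ("proprioception", "nociception", "touch"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class StimulationProtocol:
    """Ordered stimulation events: (class_id, onset s, on_duration s)."""

    events: list[tuple[int, float, float]]
    classes: list[StimulusClass]
    seed: int

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def duration(self) -> float:
        """Total protocol duration (sum of ON + OFF epochs)."""
        off = {c.class_id: c.off_duration for c in self.classes}
        return sum(on + off[cid] for cid, _, on in self.events)

    def class_by_id(self, class_id: int) -> StimulusClass:
        for c in self.classes:
            if c.class_id == class_id:
                return c
        raise KeyError(class_id)


@dataclass
class RawRecording:
    """Multichannel sampled signal with event markers and metadata."""

    samples: np.ndarray  # channels x time, nominal uV
    fs: float
    markers: list[tuple[float, int]] = field(default_factory=list)
    fsr: Optional[np.ndarray] = None
    layout: Optional[CuffLayout] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples))
        dur = self.duration
        for t, _ in self.markers:
            if not (0.0 <= t <= dur):
                raise ValueError(f"marker at {t} s outside recording of {dur} s")
        if self.fsr is not None and len(self.fsr) != self.samples.shape[1]:
            raise ValueError("fsr trace length must match the sample count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


# ---------------------------------------------------------------------------
# cuff layouts
# ---------------------------------------------------------------------------

_KNOWN_LAYOUTS = ("cuff16", "cuff3")


def build_cuff_layout(name: str) -> CuffLayout:
    """Build a canonical cuff layout.

    ``cuff16``: 4.25 mm cuff, 1.0 mm inner diameter, four rings of four
    point contacts 90 degrees apart (16 channels).  ``cuff3``: 4 mm cuff,
    1.0 mm inner diameter, three full-ring contacts 1 mm apart.
    """
    if name == "cuff16":
        length, n_rings, per_ring = 4.25, 4, 4
        # ring axial positions evenly spaced with equal end margins
        axials = [(k + 1) * length / (n_rings + 1) for k in range(n_rings)]
        contacts = []
        for r, z in enumerate(axials):
            for a in range(per_ring):
                contacts.append(
                    ContactSpec(
                        contact_id=r * per_ring + a,
                        kind="point",
                        axial_pos=z,
                        angular_pos=90.0 * a,
                    )
                )
        return CuffLayout("cuff16", length, 1.0, tuple(contacts))
    if name == "cuff3":
        contacts = tuple(
            ContactSpec(contact_id=i, kind="ring", axial_pos=1.0 + i)
            for i in range(3)
        )
        return CuffLayout("cuff3", 4.0, 1.0, contacts)
    raise ValueError(
        f"unknown cuff layout {name!r}; valid names: {', '.join(_KNOWN_LAYOUTS)}"
    )


# ---------------------------------------------------------------------------
# pickup weights
# ---------------------------------------------------------------------------

def _point_weight(px: float, py: float, fx: float, fy: float,
                  d0: float, gamma: float) -> float:
    d = np.hypot(px - fx, py - fy)
    return (d0 / (d0 + d)) ** gamma


def compute_pickup_weights(
    layout: CuffLayout,
    site: NerveSiteModel,
    ring_points: int = RING_QUADRATURE_POINTS,
) -> np.ndarray:
    """Channels x fascicles pickup-weight matrix.

    A point contact at angle phi sits on the circle of radius
    inner_diameter / 2; its weight for a fascicle is
    ``(d0 / (d0 + d)) ** gamma`` with d the cross-sectional Euclidean
    distance to the fascicle centre.  A ring contact takes the mean of the
    point formula over ``ring_points`` equally spaced angular positions.
    All weights lie in (0, 1].
    """
    if site.pickup_d0 <= 0:
        raise ValueError("pickup_d0 must be positive")
    if site.pickup_gamma <= 0:
        raise ValueError("pickup_gamma must be positive")
    radius = layout.inner_diameter / 2.0
    w = np.empty((layout.n_channels, len(site.fascicles)))
    ring_angles = np.deg2rad(np.arange(ring_points) * 360.0 / ring_points)
    for i, contact in enumerate(layout.contacts):
        for f, fas in enumerate(site.fascicles):
            fx, fy = fas.center
            if contact.kind == "point":
                phi = np.deg2rad(contact.angular_pos)
                w[i, f] = _point_weight(
                    radius * np.cos(phi), radius * np.sin(phi),
                    fx, fy, site.pickup_d0, site.pickup_gamma,
                )
            else:  # full ring: angular average of the point formula
                px = radius * np.cos(ring_angles)
                py = radius * np.sin(ring_angles)
                d = np.hypot(px - fx, py - fy)
                w[i, f] = np.mean(
                    (site.pickup_d0 / (site.pickup_d0 + d)) ** site.pickup_gamma
                )
    return w


# ---------------------------------------------------------------------------
# stimulation protocols
# ---------------------------------------------------------------------------

def generate_protocol(
    classes: Sequence[StimulusClass],
    reps_per_class_per_block: int,
    n_blocks: int,
    seed: int,
) -> StimulationProtocol:
    """Pseudo-randomised block protocol.

    Within each block every class appears exactly ``reps_per_class_per_block``
    times in a seeded random order; events are laid end-to-end (the next
    onset is the previous onset + ON + OFF).  Identical seeds reproduce the
    protocol exactly.
    """
    if not classes:
        raise ValueError("class list must not be empty")
    if reps_per_class_per_block < 1 or n_blocks < 1:
        raise ValueError("reps_per_class_per_block and n_blocks must be >= 1")
    ids = [c.class_id for c in classes]
    if len(set(ids)) != len(ids):
        raise ValueError("class_ids must be unique")
    by_id = {c.class_id: c for c in classes}
    rng = np.random.default_rng(seed)
    events: list[tuple[int, float, float]] = []
    t = 0.0
    for _ in range(n_blocks):
        order = np.repeat(ids, reps_per_class_per_block)
        rng.shuffle(order)
        for cid in order:
            c = by_id[int(cid)]
            events.append((int(cid), t, c.on_duration))
            t += c.on_duration + c.off_duration
    return StimulationProtocol(events=events, classes=list(classes), seed=seed)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _bandlimited_noise(n: int, fs: float, rng: np.random.Generator,
                       band: tuple[float, float] = SOURCE_BAND) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    lo, hi = band
    if fs <= 2 * hi:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the source band "
            f"upper edge {hi} Hz"
        )
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _amplitude_envelopes(
    protocol: StimulationProtocol,
    site: NerveSiteModel,
    class_index: dict[int, int],
    n_samples: int,
    fs: float,
    lead_in: float,
    jitter: np.ndarray,
) -> np.ndarray:
    """Fascicles x time amplitude gate: baseline plus per-class ON gains.

    ``jitter`` holds one multiplicative factor per event, applied to the ON
    gain of every fascicle alike (trial-to-trial response variability that
    preserves inter-fascicle amplitude ratios).
    """
    a = np.full((len(site.fascicles), n_samples), site.baseline_gain)
    for (cid, onset, on), j in zip(protocol.events, jitter):
        i0 = int(np.rint((lead_in + onset) * fs))
        i1 = int(np.rint((lead_in + onset + on) * fs))
        a[:, i0:i1] += j * site.gain_matrix[:, [class_index[cid]]]
    return a


def synthesize_recording(
    protocol: StimulationProtocol,
    layout: CuffLayout,
    site: NerveSiteModel,
    noise_sd: float,
    fs: float = 30000.0,
    seed: int = 0,
    *,
    noise_seed: Optional[int] = None,
    lead_in: float = 1.0,
    source_band: tuple[float, float] = SOURCE_BAND,
    trial_jitter_sd: float = 0.0,
    with_fsr: bool = False,
) -> RawRecording:
    """Simulate one cuff recording of a stimulation protocol.

    Channel i is ``sum_f w[i, f] * a_f(t) * b_f(t) + n_i(t)`` where b_f is an
    independent unit-variance band-limited Gaussian source, a_f gates the
    amplitude per the protocol (baseline during OFF, baseline + gain during
    ON), and n_i is white Gaussian contact noise.  ``seed`` drives the source
    processes; ``noise_seed`` (default: derived from ``seed``) drives the
    contact noise, so two cuffs observing the same session can share sources
    while keeping independent noise.  ``trial_jitter_sd`` > 0 draws one
    log-normal factor per event (unit mean, also seeded by ``seed`` so both
    cuffs see the same stimulus-response variability) and scales every
    fascicle's ON gain by it.  A ``lead_in`` of rest is prepended so filters
    settle before the first event; markers are emitted at every event onset
    (lead-in included).
    """
    n_classes = site.gain_matrix.shape[1]
    if n_classes != len(protocol.classes):
        raise ValueError(
            f"gain_matrix has {n_classes} class columns but the protocol "
            f"defines {len(protocol.classes)} classes"
        )
    class_index = {c.class_id: j for j, c in enumerate(protocol.classes)}
    n_samples = int(np.rint((lead_in + protocol.duration) * fs))
    w = compute_pickup_weights(layout, site)

    source_rng = np.random.default_rng(seed)
    if noise_seed is None:
        noise_seed = seed + 1_000_003
    noise_rng = np.random.default_rng(noise_seed)

    sources = np.stack(
        [_bandlimited_noise(n_samples, fs, source_rng, source_band)
         for _ in site.fascicles]
    )
    if trial_jitter_sd > 0:
        jitter_rng = np.random.default_rng(seed + 13)
        z = jitter_rng.standard_normal(protocol.n_events)
        jitter = np.exp(trial_jitter_sd * z - 0.5 * trial_jitter_sd ** 2)
    else:
        jitter = np.ones(protocol.n_events)
    amps = _amplitude_envelopes(protocol, site, class_index,
                                n_samples, fs, lead_in, jitter)
    x = w @ (amps * sources)
    if noise_sd > 0:
        x = x + noise_sd * noise_rng.standard_normal(x.shape)

    markers = [(lead_in + onset, cid) for cid, onset, _ in protocol.events]
    fsr = None
    if with_fsr:
        fsr = synthesize_fsr_trace(protocol, fs, seed + 7,
                                   lead_in=lead_in, n_samples=n_samples)
    return RawRecording(
        samples=x,
        fs=fs,
        markers=markers,
        fsr=fsr,
        layout=layout,
        meta={
            "seed": seed,
            "noise_seed": noise_seed,
            "site": site.site,
            "layout": layout.name,
            "noise_sd": noise_sd,
            "trial_jitter_sd": trial_jitter_sd,
            "lead_in": lead_in,
        },
    )


def synthesize_fsr_trace(
    protocol: StimulationProtocol,
    fs: float,
    seed: int,
    *,
    lead_in: float = 1.0,
    n_samples: Optional[int] = None,
    ramp_s: float = 0.05,
    noise_sd: float = 0.01,
) -> np.ndarray:
    """Force-sensor trace for the nociception events of a protocol.

    Near-zero noise outside ON epochs; each nociception ON epoch gets a
    trapezoid: 50 ms linear rise, plateau at a per-event amplitude drawn
    uniformly in [0.8, 1.2], 50 ms fall.  Other modalities contribute
    nothing.
    """
    if n_samples is None:
        n_samples = int(np.rint((lead_in + protocol.duration) * fs))
    rng = np.random.default_rng(seed)
    trace = noise_sd * rng.standard_normal(n_samples)
    noci = {c.class_id for c in protocol.classes if c.modality == "nociception"}
    t = np.arange(n_samples) / fs
    for cid, onset, on in protocol.events:
        if cid not in noci:
            continue
        amp = rng.uniform(0.8, 1.2)
        t0 = lead_in + onset
        rel = t - t0
        up = np.clip(rel / ramp_s, 0.0, 1.0)
        down = np.clip((on - rel) / ramp_s, 0.0, 1.0)
        trace += amp * np.where((rel >= 0) & (rel <= on),
                                np.minimum(up, down), 0.0)
    return trace


# ---------------------------------------------------------------------------
# default class sets and site models
# ---------------------------------------------------------------------------

PROPRIO_ANGLES = (-30, -20, -10, 10, 20, 30)

#: invented per-class gains for the third (cutaneous/sural) fascicle
_CUTANEOUS_GAINS = {
    "heel_pinch": 1.5,
    "toe_pinch": 1.0,
    "touch_heavy": 0.5,
    "touch_light": 0.3,
}


def proprioception_classes(on_s: float = 3.0, off_s: float = 3.0,
                           start_id: int = 0) -> list[StimulusClass]:
    """The six proprioceptive joint-angle classes (+-10/20/30 degrees)."""
    return [
        StimulusClass(start_id + i, f"{a:+d}deg", "proprioception", on_s, off_s)
        for i, a in enumerate(PROPRIO_ANGLES)
    ]


def ten_class_set(on_s: float = 3.0, off_s: float = 3.0,
                  noci_on_s: float = 3.0, noci_off_s: float = 3.0
                  ) -> list[StimulusClass]:
    """Ten-class set: six angles, two pinch sites, two touch intensities."""
    classes = proprioception_classes(on_s, off_s)
    nid = len(classes)
    classes += [
        StimulusClass(nid, "heel_pinch", "nociception", noci_on_s, noci_off_s),
        StimulusClass(nid + 1, "toe_pinch", "nociception", noci_on_s, noci_off_s),
        StimulusClass(nid + 2, "touch_heavy", "touch", on_s, off_s),
        StimulusClass(nid + 3, "touch_light", "touch", on_s, off_s),
    ]
    return classes


def _default_gain_matrix(classes: Sequence[StimulusClass],
                         n_fascicles: int) -> np.ndarray:
    """Default activation gains.

    Proprioception: gain (|angle| / 30) * (1 + [fascicle matches the angle
    sign]) with the tibial fascicle responding to negative angles and the
    peroneal to positive ones — encodes both the magnitude effect (larger
    |angle| raises every channel's MAV) and the sign effect (the
    tibial/peroneal amplitude ratio flips with the angle sign).
    Nociception/touch drive the third (cutaneous) fascicle with fixed gains.
    """
    g = np.zeros((n_fascicles, len(classes)))
    for j, c in enumerate(classes):
        if c.modality == "proprioception":
            angle = float(c.label.replace("deg", ""))
            mag = abs(angle) / 30.0
            g[0, j] = mag * (2.0 if angle < 0 else 1.0)  # tibial
            g[1, j] = mag * (2.0 if angle > 0 else 1.0)  # peroneal
        else:
            if n_fascicles < 3:
                raise ValueError(
                    "nociception/touch classes need the cutaneous fascicle"
                )
            g[2, j] = _CUTANEOUS_GAINS[c.label]
    return g


#: fascicle centre offsets (mm).  Distally the tibial and peroneal
#: fascicles are well separated; proximally they are nearly concentric, so
#: contact-to-contact pickup ratios are almost flat and only overall
#: amplitude carries information.
SITE_OFFSETS = {"distal": 0.3, "proximal": 0.002}


def make_site_model(
    site: str,
    classes: Sequence[StimulusClass],
    *,
    baseline_gain: float = 0.1,
    pickup_d0: float = 0.1,
    pickup_gamma: float = 2.0,
) -> NerveSiteModel:
    """Default two/three-fascicle site model for a class set.

    A cutaneous fascicle is added only when the class set includes
    nociception or touch classes.
    """
    if site not in SITE_OFFSETS:
        raise ValueError(
            f"unknown site {site!r}; valid sites: {', '.join(SITE_OFFSETS)}"
        )
    off = SITE_OFFSETS[site]
    need_cutaneous = any(c.modality in ("nociception", "touch") for c in classes)
    fascicles = [
        FascicleSpec("tibial", (-off, 0.0), 0.12),
        FascicleSpec("peroneal", (off, 0.0), 0.12),
    ]
    if need_cutaneous:
        fascicles.append(FascicleSpec("cutaneous", (0.0, off), 0.08))
    gain = _default_gain_matrix(classes, len(fascicles))
    return NerveSiteModel(
        site=site,
        fascicles=fascicles,
        gain_matrix=gain,
        baseline_gain=baseline_gain,
        pickup_d0=pickup_d0,
        pickup_gamma=pickup_gamma,
    )
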