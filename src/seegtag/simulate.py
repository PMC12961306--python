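"""Synthetic frequency-tagged sEEG generator with known ground truth.

Emulates the study design this package analyzes: 10-s isochronous
Mandarin-style speech sequences of 250-ms syllables, presented in three
conditions (syllables, two-syllable phrases, two-phrase sentences) that
tag the linguistic hierarchy at 4, 2, and 1 Hz; 40 trials per condition;
multi-contact depth-electrode recordings at 512 Hz (one subject at
2048 Hz) with 1/f background noise.

Each synthetic contact carries:

* phase-locked sinusoids at its ground-truth tagged rates (phase fixed
  across trials, or von Mises-jittered when a finite ``phase_kappa`` is
  set), active only while the stimulus is on;
* a 60--100 Hz band-limited noise carrier whose amplitude envelope is
  ``1 + sum_f m sin(2 pi f t + phi_f)`` for the tags it modulates --
  band-limited noise rather than a pure tone, so the low-frequency
  broadband spectrum contains no tag energy from the carrier and
  envelope tracking can be dissociated from broadband tracking;
* 1/f-shaped Gaussian noise (unit standard deviation), exponent 1.0.

Ground truth (which tags are locked where, at what strength) is
recorded per contact so downstream detection and classification can be
scored against it. ROI response profiles are a coarse emulation of the
fronto-temporal response topography reported for this paradigm, not a
quantitative model of any real dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectral import EpochedTrials, epoch_trials

logger = logging.getLogger(__name__)

CONDITIONS = ("syllable", "phrase", "sentence")

#: Tagged rates (Hz) present in each condition's linguistic structure.
TAGGED_RATES: dict[str, tuple[float, ...]] = {
    "syllable": (4.0,),
    "phrase": (4.0, 2.0),
    "sentence": (4.0, 2.0, 1.0),
}

ROIS = ("HG", "STG", "MTG", "ITG", "IFG", "other")

SYLLABLE_DURATION = 0.25  # s
TRIAL_DURATION = 10.0  # s
N_SYLLABLES = 40

#: Per-(ROI, condition) probability that a contact phase-locks at a tag.
#: Coarse emulation of the reported fronto-temporal topography: primary
#: auditory cortex (HG) locks to the syllabic rate almost always, the
#: superior temporal gyrus tracks all levels, and IFG preferentially
#: tracks the higher-order phrasal/sentential structures.
DEFAULT_ROI_PROFILE: dict[str, dict[str, dict[float, float]]] = {
    "HG": {
        "syllable": {4.0: 0.95},
        "phrase": {4.0: 0.90, 2.0: 0.30},
        "sentence": {4.0: 0.95, 2.0: 0.40, 1.0: 0.15},
    },
    "STG": {
        "syllable": {4.0: 0.85},
        "phrase": {4.0: 0.85, 2.0: 0.45},
        "sentence": {4.0: 0.85, 2.0: 0.50, 1.0: 0.30},
    },
    "MTG": {
        "syllable": {4.0: 0.33},
        "phrase": {4.0: 0.37, 2.0: 0.13},
        "sentence": {4.0: 0.44, 2.0: 0.12, 1.0: 0.06},
    },
    "ITG": {
        "syllable": {4.0: 0.18},
        "phrase": {4.0: 0.25, 2.0: 0.03},
        "sentence": {4.0: 0.25, 2.0: 0.04, 1.0: 0.03},
    },
    "IFG": {
        "syllable": {4.0: 0.25},
        "phrase": {4.0: 0.10, 2.0: 0.05},
        "sentence": {4.0: 0.20, 2.0: 0.15, 1.0: 0.25},
    },
    "other": {
        "syllable": {4.0: 0.15},
        "phrase": {4.0: 0.15, 2.0: 0.04},
        "sentence": {4.0: 0.17, 2.0: 0.05, 1.0: 0.04},
    },
}

#: Probability that a contact's high-gamma carrier is amplitude-modulated
#: at its locked tags (envelope tracking is sparser than broadband).
DEFAULT_HG_PROB: dict[str, float] = {
    "HG": 0.50, "STG": 0.30, "MTG": 0.08, "ITG": 0.05, "IFG": 0.15, "other": 0.03,
}

#: Rough MNI centroids (mm) used to place synthetic contacts; x sign
#: flips with hemisphere.
_ROI_MNI = {
    "HG": (42.0, -20.0, 8.0),
    "STG": (58.0, -20.0, 5.0),
    "MTG": (57.0, -35.0, -5.0),
    "ITG": (50.0, -40.0, -20.0),
    "IFG": (48.0, 25.0, 10.0),
    "other": (35.0, -20.0, 20.0),
}

#: ROI sampling probabilities per hemisphere, shaped after the relative
#: fronto-temporal contact counts of a typical clinical sEEG cohort.
DEFAULT_ROI_PROBS = {
    "L": {"HG": 0.018, "STG": 0.070, "MTG": 0.145, "ITG": 0.053,
          "IFG": 0.031, "other": 0.683},
    "R": {"HG": 0.009, "STG": 0.045, "MTG": 0.141, "ITG": 0.118,
          "IFG": 0.051, "other": 0.636},
}

# Per-subject defaults mirroring a 20-subject clinical cohort: contact
# counts, implanted hemisphere(s), and sampling rate (one subject's
# clinical amplifier ran at 2048 Hz, the rest at 512 Hz).
DEFAULT_CONTACT_COUNTS = (84, 93, 88, 105, 61, 46, 67, 88, 98, 96,
                          125, 87, 101, 82, 85, 100, 80, 108, 83, 66)
DEFAULT_HEMISPHERES = ("LR", "L", "LR", "L", "LR", "LR", "L", "L", "R", "R",
                       "LR", "L", "LR", "L", "L", "L", "L", "L", "R", "L")
DEFAULT_SFREQS = tuple(2048.0 if i == 4 else 512.0 for i in range(20))


class SimulationError(ValueError):
    """Raised on invalid simulation parameters."""


@dataclass(frozen=True)
class StimulusTimeline:
    """Timing skeleton of one 10-s trial in a given condition."""

    condition: str
    syllable_duration: float = SYLLABLE_DURATION
    trial_duration: float = TRIAL_DURATION
    tagged_rates: tuple[float, ...] = ()
    event_onsets: tuple[float, ...] = ()


def build_stimulus_timeline(condition: str) -> StimulusTimeline:
    """Syllable onsets and tagged rates for one condition.

    40 syllables of 250 ms each tile the 10-s trial without gaps, so
    syllables recur at 4 Hz; two-syllable phrases add a 2 Hz rate and
    two-phrase sentences a 1 Hz rate.
    """
    if condition not in TAGGED_RATES:
        raise SimulationError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    onsets = tuple(np.round(np.arange(N_SYLLABLES) * SYLLABLE_DURATION, 10))
    return StimulusTimeline(
        condition=condition,
        tagged_rates=TAGGED_RATES[condition],
        event_onsets=onsets,
    )


@dataclass
class ContactTruth:
    """Ground-truth generative parameters for one synthetic contact."""

    contact_id: str
    subject_id: str
    roi: str
    hemisphere: str
    locked_tags: dict[str, tuple[float, ...]]  # condition -> Hz
    hg_modulated_tags: dict[str, tuple[float, ...]] = field(default_factory=dict)
    locking_strength: float = 0.2  # sinusoid amplitude / noise SD
    hg_depth: float = 0.4  # AM modulation depth m
    hg_scale: float = 0.5  # carrier SD / noise SD
    noise_exponent: float = 1.0  # 1/f spectral slope
    phase_kappa: float | None = None  # None => trial-invariant phase
    mni_xyz: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise SimulationError(f"hemisphere must be L or R, got {self.hemisphere!r}")
        if self.roi not in ROIS:
            raise SimulationError(f"unknown ROI {self.roi!r}")
        if self.locking_strength < 0:
            raise SimulationError("locking_strength must be >= 0")
        for cond, tags in self.locked_tags.items():
            extra = set(tags) - set(TAGGED_RATES[cond])
            if extra:
                raise SimulationError(
                    f"locked tags {sorted(extra)} not tagged in condition {cond!r}"
                )
        for cond, tags in self.hg_modulated_tags.items():
            extra = set(tags) - set(TAGGED_RATES[cond])
            if extra:
                raise SimulationError(
                    f"high-gamma tags {sorted(extra)} not tagged in condition {cond!r}"
                )


def one_over_f_noise(
    rng: np.random.Generator, n: int, sfreq: float, exponent: float = 1.0
) -> np.ndarray:
    """Unit-SD Gaussian noise with power spectrum ~ 1/f**exponent.

    White Gaussian noise is shaped in the frequency domain (amplitude
    scaled by f**(-exponent/2), DC zeroed), then normalized. Internally
    computed at the next fast FFT length and truncated to ``n``.
    """
    from scipy.fft import next_fast_len

    if exponent == 0:
        return rng.standard_normal(n)
    m = next_fast_len(n)
    white = rng.standard_normal(m)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(m, d=1.0 / sfreq)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=m)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def bandlimited_noise(
    rng: np.random.Generator, n: int, sfreq: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to [lo, hi] Hz."""
    if hi >= sfreq / 2:
        raise SimulationError(
            f"band edge {hi} Hz not resolvable at {sfreq} Hz (Nyquist {sfreq / 2} Hz)"
        )
    from scipy.fft import next_fast_len

    m = next_fast_len(n)
    white = rng.standard_normal(m)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(m, d=1.0 / sfreq)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n=m)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _tag_phases(
    rng: np.random.Generator, tags: tuple[float, ...]
) -> dict[float, float]:
    # one fixed phase per tag, drawn from the contact's seeded stream
    return {tag: float(rng.uniform(0.0, 2.0 * np.pi)) for tag in sorted(tags)}


def draw_trial_onsets(
    rng: np.random.Generator,
    n_trials: int,
    iti_range: tuple[float, float] = (1.0, 2.0),
    lead_in: float = 2.0,
) -> np.ndarray:
    """Stimulus onsets (s) for ``n_trials`` 10-s trials with random ITIs."""
    itis = rng.uniform(iti_range[0], iti_range[1], size=max(n_trials - 1, 0))
    return lead_in + np.concatenate(([0.0], np.cumsum(TRIAL_DURATION + itis)))


def simulate_contact_condition(
    truth: ContactTruth,
    condition: str,
    n_trials: int = 40,
    sfreq: float = 512.0,
    iti_range: tuple[float, float] = (1.0, 2.0),
    lead_in: float = 2.0,
    onsets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous recording for one contact and condition.

    Returns ``(signal, onsets)``: a single-channel continuous signal
    containing ``n_trials`` 10-s stimulation periods separated by silent
    1--2 s inter-trial intervals, and the stimulus onsets in seconds.
    Background noise and the high-gamma carrier run continuously;
    stimulus-locked components are added only while the stimulus is on.

    ``onsets`` may be supplied to share one presentation schedule across
    all contacts of a subject (they hear the same stimuli); otherwise a
    schedule is drawn from the contact's own stream.

    Deterministic in ``(truth.seed, condition, onsets)``: repeated calls
    yield identical arrays.
    """
    if condition not in TAGGED_RATES:
        raise SimulationError(f"unknown condition {condition!r}")
    if n_trials < 1:
        raise SimulationError("n_trials must be >= 1")
    if sfreq < 256.0:
        raise SimulationError(
            f"sampling rate {sfreq} Hz cannot resolve the 60-100 Hz band; need >= 256"
        )
    for tag in truth.locked_tags.get(condition, ()):
        if tag >= sfreq / 2:
            raise SimulationError(f"tag {tag} Hz not resolvable at {sfreq} Hz")

    cond_index = CONDITIONS.index(condition)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=truth.seed, spawn_key=(cond_index,))
    )

    locked = truth.locked_tags.get(condition, ())
    hg_tags = truth.hg_modulated_tags.get(condition, ())
    phases = _tag_phases(rng, tuple(set(locked) | set(hg_tags)))

    if onsets is None:
        onsets = draw_trial_onsets(rng, n_trials, iti_range, lead_in)
    else:
        onsets = np.asarray(onsets, dtype=float)
        if onsets.size != n_trials:
            raise SimulationError(
                f"{onsets.size} onsets supplied for {n_trials} trials"
            )
    total = onsets[-1] + TRIAL_DURATION + iti_range[1]
    n_samp = int(np.ceil(total * sfreq))

    signal = one_over_f_noise(rng, n_samp, sfreq, truth.noise_exponent)
    carrier = truth.hg_scale * bandlimited_noise(rng, n_samp, sfreq, 60.0, 100.0)

    n_stim = int(round(TRIAL_DURATION * sfreq))
    t_stim = np.arange(n_stim) / sfreq
    for onset in onsets:
        i0 = int(round(onset * sfreq))
        sl = slice(i0, i0 + n_stim)
        if locked:
            add = np.zeros(n_stim)
            for tag in locked:
                phi = phases[tag]
                if truth.phase_kappa is not None and np.isfinite(truth.phase_kappa):
                    phi = float(rng.vonmises(phi, truth.phase_kappa))
                add += truth.locking_strength * np.sin(2 * np.pi * tag * t_stim + phi)
            signal[sl] += add
        if hg_tags:
            env = np.ones(n_stim)
            for tag in hg_tags:
                env += truth.hg_depth * np.sin(2 * np.pi * tag * t_stim + phases[tag])
            carrier[sl] *= env
    return signal + carrier, onsets


def simulate_contact_trials(
    truth: ContactTruth,
    condition: str,
    n_trials: int = 40,
    sfreq: float = 512.0,
    window: tuple[float, float] = (-0.5, 10.0),
) -> EpochedTrials:
    """Epoched trials (default window -0.5 to 10 s) for one contact/condition."""
    signal, onsets = simulate_contact_condition(truth, condition, n_trials, sfreq)
    return epoch_trials(
        signal, sfreq, onsets, window,
        contact_id=truth.contact_id, condition=condition,
    )


@dataclass
class StudyConfig:
    """Design of a synthetic study.

    Defaults reproduce the emulated clinical cohort: 20 subjects with
    46--125 contacts each, 3 conditions x 40 trials of 10-s stimulation,
    512 Hz sampling (subject 5 at 2048 Hz).
    """

    n_subjects: int = 20
    contact_counts: tuple[int, ...] = DEFAULT_CONTACT_COUNTS
    hemispheres: tuple[str, ...] = DEFAULT_HEMISPHERES
    sfreqs: tuple[float, ...] = DEFAULT_SFREQS
    n_trials: int = 40
    locking_strength: float = 0.2
    hg_depth: float = 0.4
    hg_scale: float = 0.5
    noise_exponent: float = 1.0
    iti_range: tuple[float, float] = (1.0, 2.0)
    null_truth: bool = False  # if True, no contact locks to anything

    def __post_init__(self) -> None:
        def _take(seq, fill):
            seq = tuple(seq)
            if len(seq) >= self.n_subjects:
                return seq[: self.n_subjects]
            return seq + tuple(fill for _ in range(self.n_subjects - len(seq)))

        self.contact_counts = _take(self.contact_counts, 80)
        self.hemispheres = _take(self.hemispheres, "L")
        self.sfreqs = _take(self.sfreqs, 512.0)
        if self.n_trials < 1:
            raise SimulationError("n_trials must be >= 1")


@dataclass
class SyntheticStudy:
    """In-memory handle on a generated study: truth plus design."""

    config: StudyConfig
    truth: list[ContactTruth]
    master_seed: int

    def truth_by_id(self) -> dict[str, ContactTruth]:
        return {t.contact_id: t for t in self.truth}


def _sample_roi(rng: np.random.Generator, hemisphere: str) -> str:
    probs = DEFAULT_ROI_PROBS[hemisphere]
    names = list(probs)
    p = np.array([probs[r] for r in names])
    return str(rng.choice(names, p=p / p.sum()))


def build_truth_table(
    config: StudyConfig, master_seed: int,
    roi_profile: dict | None = None,
    hg_prob: dict[str, float] | None = None,
) -> SyntheticStudy:
    """Draw per-contact ground truth for a whole study.

    Contact seeds are spawned deterministically from ``master_seed``;
    the same master seed always yields the same truth table.
    """
    roi_profile = roi_profile or DEFAULT_ROI_PROFILE
    hg_prob = hg_prob or DEFAULT_HG_PROB
    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    truth: list[ContactTruth] = []
    for s in range(config.n_subjects):
        subject_id = f"sub-{s + 1:02d}"
        implant = config.hemispheres[s]
        for c in range(config.contact_counts[s]):
            hemi = implant if implant in ("L", "R") else ("L" if rng.random() < 0.5 else "R")
            roi = _sample_roi(rng, hemi)
            locked: dict[str, tuple[float, ...]] = {}
            hg_mod: dict[str, tuple[float, ...]] = {}
            if not config.null_truth:
                profile = roi_profile[roi]
                hg_on = rng.random() < hg_prob[roi]
                for cond in CONDITIONS:
                    tags = tuple(
                        tag for tag, p in sorted(profile.get(cond, {}).items())
                        if rng.random() < p
                    )
                    if tags:
                        locked[cond] = tags
                        if hg_on:
                            hg_mod[cond] = tags
            cx, cy, cz = _ROI_MNI[roi]
            x = (cx if hemi == "R" else -cx) + rng.normal(0, 4)
            mni = (round(float(x), 1),
                   round(float(cy + rng.normal(0, 6)), 1),
                   round(float(cz + rng.normal(0, 6)), 1))
            # independent per-contact seed, kept below 2**31
            seed = int(rng.integers(0, 2**31 - 1))
            truth.append(ContactTruth(
                contact_id=f"{subject_id}_ch{c + 1:03d}",
                subject_id=subject_id,
                roi=roi,
                hemisphere=hemi,
                locked_tags=locked,
                hg_modulated_tags=hg_mod,
                locking_strength=config.locking_strength,
                hg_depth=config.hg_depth,
                hg_scale=config.hg_scale,
                noise_exponent=config.noise_exponent,
                mni_xyz=mni,
                seed=seed,
            ))
    return SyntheticStudy(config=config, truth=truth, master_seed=master_seed)


def simulate_subject_recording(
    study: SyntheticStudy, subject_id: str, block_gap: float = 5.0
) -> tuple[np.ndarray, float, list[str], "pd.DataFrame"]:
    """Assemble one subject's continuous multi-channel recording.

    The three condition blocks are concatenated (syllable, phrase,
    sentence) with ``block_gap`` seconds between blocks. Returns
    ``(data, sfreq, channel_names, events)`` where ``data`` is
    channels x samples (float32) and ``events`` has columns
    trial_id / condition / onset / duration.
    """
    import pandas as pd

    config = study.config
    contacts = [t for t in study.truth if t.subject_id == subject_id]
    if not contacts:
        raise SimulationError(f"no contacts for subject {subject_id!r}")
    s_index = int(subject_id.split("-")[1]) - 1
    sfreq = config.sfreqs[s_index]

    chunks: list[np.ndarray] = []
    rows = []
    offset = 0.0
    for ci, cond in enumerate(CONDITIONS):
        # one presentation schedule per (subject, condition), shared by
        # every contact: all contacts hear the same stimulus sequence
        sched_rng = np.random.default_rng(np.random.SeedSequence(
            entropy=study.master_seed, spawn_key=(7, s_index, ci)))
        onsets = draw_trial_onsets(sched_rng, config.n_trials, config.iti_range)
        block = None
        for i, truth in enumerate(contacts):
            sig, _ = simulate_contact_condition(
                truth, cond, config.n_trials, sfreq, config.iti_range,
                onsets=onsets,
            )
            if block is None:
                block = np.empty((len(contacts), sig.size), dtype=np.float32)
            block[i] = sig
        chunks.append(block)
        for k, onset in enumerate(onsets):
            rows.append({
                "trial_id": f"{cond}-{k + 1:02d}",
                "condition": cond,
                "onset": round(offset + float(onset), 6),
                "duration": TRIAL_DURATION,
            })
        offset += block.shape[1] / sfreq + block_gap
        chunks.append(np.zeros((len(contacts), int(round(block_gap * sfreq))),
                               dtype=np.float32))
    data = np.concatenate(chunks[:-1], axis=1)  # no trailing gap
    names = [t.contact_id for t in contacts]
    events = pd.DataFrame(rows)
    return data, sfreq, names, events


def simulate_study(
    config: StudyConfig, master_seed: int, out_dir
) -> SyntheticStudy:
    """Generate a full synthetic study and write it to disk.

    Layout under ``out_dir``::

        sub-XX/sub-XX_ieeg.edf        continuous recording, all 3 blocks
        sub-XX/sub-XX_channels.tsv    channel names / units / rate
        sub-XX/sub-XX_electrodes.tsv  MNI coordinates, hemisphere, ROI
        sub-XX/sub-XX_events.tsv      trial onsets and conditions
        truth.tsv                     ground-truth generative parameters
        manifest.json                 master seed and design parameters

    Deterministic: the same ``(config, master_seed)`` reproduces every
    output byte.
    """
    import json
    from dataclasses import asdict
    from pathlib import Path

    import pandas as pd

    from . import io as io_formats

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study = build_truth_table(config, master_seed)

    subject_ids = sorted({t.subject_id for t in study.truth})
    for subject_id in subject_ids:
        sub_dir = out_dir / subject_id
        sub_dir.mkdir(exist_ok=True)
        data, sfreq, names, events = simulate_subject_recording(study, subject_id)
        io_formats.write_edf(sub_dir / f"{subject_id}_ieeg.edf", data, sfreq, names)
        io_formats.write_tsv(
            pd.DataFrame({
                "name": names,
                "type": "SEEG",
                "units": "uV",
                "sampling_frequency": sfreq,
            }),
            sub_dir / f"{subject_id}_channels.tsv",
        )
        contacts = [t for t in study.truth if t.subject_id == subject_id]
        io_formats.write_tsv(
            pd.DataFrame({
                "name": [t.contact_id for t in contacts],
                "subject_id": subject_id,
                "hemisphere": [t.hemisphere for t in contacts],
                "roi": [t.roi for t in contacts],
                "x": [t.mni_xyz[0] for t in contacts],
                "y": [t.mni_xyz[1] for t in contacts],
                "z": [t.mni_xyz[2] for t in contacts],
                "sampling_rate": sfreq,
            }),
            sub_dir / f"{subject_id}_electrodes.tsv",
        )
        io_formats.write_tsv(events, sub_dir / f"{subject_id}_events.tsv")
        logger.info("wrote %s: %d contacts, %d events",
                    subject_id, len(contacts), len(events))

    io_formats.write_tsv(io_formats.truth_to_frame(study.truth),
                         out_dir / "truth.tsv")
    manifest = {
        "master_seed": master_seed,
        "config": asdict(config),
        "n_subjects": len(subject_ids),
        "n_contacts": len(study.truth),
        "conditions": list(CONDITIONS),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n"
    )
    return study
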