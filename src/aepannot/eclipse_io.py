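"""Read and write raw auditory-evoked-potential recordings as XML.

Clinical evoked-potential systems export each averaged recording as an XML
file whose payload is a pair of interleaved sweep buffers (``IPSI_A_RAW`` and
``IPSI_B_RAW``) together with the acquisition metadata needed to reconstruct
the stimulus-locked waveform (``SampleRate``, ``PrestimulusSamples``) and,
when a clinician has marked waves on the device, their sample positions
(``Jewetts``).  This module defines and parses a minimal, documented dialect
built from those field names (schema in ``docs/recording.xsd``): one
recording per file, samples as whitespace-separated decimal text, wave
positions as 0-based sample indices.  It makes no attempt at
bit-compatibility with any proprietary header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

__all__ = [
    "ABR",
    "AMLR",
    "SUBTYPES",
    "ABR_WAVES",
    "AMLR_WAVES",
    "WAVE_LABELS",
    "RawRecording",
    "RecordingError",
    "RecordingParseError",
    "MissingBufferError",
    "BufferMismatchError",
    "read_recording_xml",
    "write_recording_xml",
]

ABR = "ABR"
AMLR = "AMLR"
SUBTYPES = (ABR, AMLR)

#: Canonical wave order per subtype (ABR Jewett peaks; AMLR components).
ABR_WAVES = ("I", "II", "III", "IV", "V")
AMLR_WAVES = ("Na", "Pa", "Nb", "Pb")
WAVE_LABELS = {ABR: ABR_WAVES, AMLR: AMLR_WAVES}

_EARS = ("left", "right", "unknown")

_ROOT_TAG = "AEPRecording"


class RecordingError(ValueError):
    """Base class for recording I/O and validation failures."""


class RecordingParseError(RecordingError):
    """The XML file is malformed or missing a required element."""


class MissingBufferError(RecordingParseError):
    """``IPSI_A_RAW`` or ``IPSI_B_RAW`` is absent."""


class BufferMismatchError(RecordingError):
    """The two sweep buffers have different lengths (or are empty)."""


@dataclass
class RawRecording:
    """One exported recording, prior to averaging, scaling or filtering.

    Parameters
    ----------
    subtype
        ``"ABR"`` or ``"AMLR"``.
    buffer_a, buffer_b
        The two interleaved sweep sub-averages, in raw device units.
    sample_rate
        Sampling rate in Hz (30 kHz for ABR, 3 kHz for AMLR at the standard
        450-sample geometry).
    prestimulus_samples
        Samples acquired before stimulus completion.  Carried as metadata
        only: the device aligns sample 0 with stimulus completion, so the
        reconstructed time axis starts at 0 ms.
    raw_to_microvolt
        Multiplicative factor converting raw units to microvolts.
    stimulus_intensity
        Stimulus level in dB nHL (``None`` if unknown).
    ear
        ``"left"``, ``"right"`` or ``"unknown"``.
    patient_id
        Opaque identifier; doubles as the recording id for reports.
    gold_waves
        Optional clinician annotations: wave label -> 0-based sample index.
    """

    subtype: str
    buffer_a: np.ndarray
    buffer_b: np.ndarray
    sample_rate: float
    prestimulus_samples: int = 0
    raw_to_microvolt: float = 1.0
    stimulus_intensity: float | None = None
    ear: str = "unknown"
    patient_id: str = ""
    gold_waves: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.buffer_a = np.asarray(self.buffer_a, dtype=float)
        self.buffer_b = np.asarray(self.buffer_b, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.buffer_a.size)

    def validate(self) -> None:
        """Raise :class:`RecordingError` if any structural invariant fails."""
        if self.subtype not in SUBTYPES:
            raise RecordingError(f"unknown subtype {self.subtype!r}")
        if self.buffer_a.ndim != 1 or self.buffer_b.ndim != 1:
            raise RecordingError("buffers must be one-dimensional")
        if self.buffer_a.size == 0:
            raise BufferMismatchError("buffers must be non-empty")
        if self.buffer_a.size != self.buffer_b.size:
            raise BufferMismatchError(
                f"buffer length mismatch: IPSI_A_RAW has {self.buffer_a.size} "
                f"samples, IPSI_B_RAW has {self.buffer_b.size}"
            )
        if not self.sample_rate > 0:
            raise RecordingError("sample_rate must be positive")
        if self.prestimulus_samples < 0:
            raise RecordingError("prestimulus_samples must be >= 0")
        if self.ear not in _EARS:
            raise RecordingError(f"ear must be one of {_EARS}")
        if self.gold_waves is not None:
            known = WAVE_LABELS[self.subtype]
            for label, idx in self.gold_waves.items():
                if label not in known:
                    raise RecordingError(
                        f"gold wave {label!r} is not a {self.subtype} wave"
                    )
                if not 0 <= int(idx) < self.n_samples:
                    raise RecordingError(
                        f"gold wave {label} index {idx} outside [0, {self.n_samples})"
                    )

    def equals(self, other: "RawRecording", rtol: float = 1e-9) -> bool:
        """Field-by-field equality (floats compared to relative tolerance)."""
        if (
            self.subtype != other.subtype
            or self.prestimulus_samples != other.prestimulus_samples
            or self.ear != other.ear
            or self.patient_id != other.patient_id
            or (self.gold_waves or None) != (other.gold_waves or None)
        ):
            return False
        for a, b in (
            (self.sample_rate, other.sample_rate),
            (self.raw_to_microvolt, other.raw_to_microvolt),
        ):
            if not math.isclose(a, b, rel_tol=rtol, abs_tol=rtol):
                return False
        if (self.stimulus_intensity is None) != (other.stimulus_intensity is None):
            return False
        if self.stimulus_intensity is not None and not math.isclose(
            self.stimulus_intensity, other.stimulus_intensity, rel_tol=rtol, abs_tol=rtol
        ):
            return False
        return (
            self.buffer_a.size == other.buffer_a.size
            and np.allclose(self.buffer_a, other.buffer_a, rtol=rtol, atol=0)
            and np.allclose(self.buffer_b, other.buffer_b, rtol=rtol, atol=0)
        )


def _fmt(x: float) -> str:
    # 17 significant digits round-trips IEEE doubles exactly.
    return format(float(x), ".17g")


def _child_text(root: ET.Element, tag: str, path: Path) -> str:
    el = root.find(tag)
    if el is None or el.text is None:
        raise RecordingParseError(f"{path}: missing element <{tag}>")
    return el.text.strip()


def read_recording_xml(path: str | Path) -> RawRecording:
    """Parse one recording from *path*.

    Raw buffer values are returned untouched: they are neither averaged nor
    converted to microvolts (see :mod:`aepannot.preprocess` for that).
    ``gold_waves`` is ``None`` when the file carries no ``Jewetts`` element.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise RecordingParseError(f"{path}: malformed XML ({exc})") from exc
    root = tree.getroot()
    if root.tag != _ROOT_TAG:
        raise RecordingParseError(
            f"{path}: root element is <{root.tag}>, expected <{_ROOT_TAG}>"
        )

    buffers: dict[str, np.ndarray] = {}
    for tag in ("IPSI_A_RAW", "IPSI_B_RAW"):
        el = root.find(tag)
        if el is None:
            raise MissingBufferError(f"{path}: missing buffer element <{tag}>")
        text = el.text or ""
        try:
            values = np.array([float(v) for v in text.split()], dtype=float)
        except ValueError as exc:
            raise RecordingParseError(
                f"{path}: non-numeric sample in <{tag}> ({exc})"
            ) from exc
        buffers[tag] = values

    subtype = _child_text(root, "Subtype", path)
    if subtype not in SUBTYPES:
        raise RecordingParseError(f"{path}: unknown <Subtype> {subtype!r}")

    def _float_of(tag: str) -> float:
        text = _child_text(root, tag, path)
        try:
            return float(text)
        except ValueError as exc:
            raise RecordingParseError(f"{path}: non-numeric <{tag}>") from exc

    intensity_el = root.find("Intensity")
    intensity = None
    if intensity_el is not None and intensity_el.text and intensity_el.text.strip():
        intensity = float(intensity_el.text)

    ear_el = root.find("Ear")
    ear = ear_el.text.strip() if ear_el is not None and ear_el.text else "unknown"
    pid_el = root.find("PatientID")
    patient_id = pid_el.text.strip() if pid_el is not None and pid_el.text else ""

    gold: dict[str, int] | None = None
    jewetts = root.find("Jewetts")
    if jewetts is not None:
        gold = {}
        for wave_el in jewetts.findall("Jewett"):
            label = wave_el.get("Wave")
            sample = wave_el.get("Sample")
            if label is None or sample is None:
                raise RecordingParseError(
                    f"{path}: <Jewett> needs Wave and Sample attributes"
                )
            gold[label] = int(sample)
        if not gold:
            gold = None

    rec = RawRecording(
        subtype=subtype,
        buffer_a=buffers["IPSI_A_RAW"],
        buffer_b=buffers["IPSI_B_RAW"],
        sample_rate=_float_of("SampleRate"),
        prestimulus_samples=int(_child_text(root, "PrestimulusSamples", path)),
        raw_to_microvolt=_float_of("RawToMicrovolt"),
        stimulus_intensity=intensity,
        ear=ear,
        patient_id=patient_id,
        gold_waves=gold,
    )
    rec.validate()
    return rec


def write_recording_xml(rec: RawRecording, path: str | Path) -> None:
    """Serialize *rec* so that :func:`read_recording_xml` recovers it."""
    rec.validate()
    root = ET.Element(_ROOT_TAG)
    ET.SubElement(root, "Subtype").text = rec.subtype
    ET.SubElement(root, "PatientID").text = rec.patient_id
    ET.SubElement(root, "Ear").text = rec.ear
    if rec.stimulus_intensity is not None:
        ET.SubElement(root, "Intensity").text = _fmt(rec.stimulus_intensity)
    ET.SubElement(root, "SampleRate").text = _fmt(rec.sample_rate)
    ET.SubElement(root, "PrestimulusSamples").text = str(rec.prestimulus_samples)
    ET.SubElement(root, "RawToMicrovolt").text = _fmt(rec.raw_to_microvolt)
    ET.SubElement(root, "IPSI_A_RAW").text = " ".join(_fmt(v) for v in rec.buffer_a)
    ET.SubElement(root, "IPSI_B_RAW").text = " ".join(_fmt(v) for v in rec.buffer_b)
    if rec.gold_waves:
        jewetts = ET.SubElement(root, "Jewetts")
        order = WAVE_LABELS[rec.subtype]
        for label in sorted(rec.gold_waves, key=order.index):
            ET.SubElement(
                jewetts,
                "Jewett",
                Wave=label,
                Sample=str(int(rec.gold_waves[label])),
            )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
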