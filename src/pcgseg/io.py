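"""Reading, writing and reshaping phonocardiogram records and their annotations.

A PCG annotation is a region table: ordered (start, end, class) rows over
1-based sample indices in which consecutive rows share their boundary
(each row's start equals the previous row's end) and classes cycle through
the cardiac phases S1 -> systolic -> S2 -> diastolic.  For training, region
tables are expanded to one label per signal sample; predictions are
collapsed back to tables for writing.

Indexing convention: region-table files are 1-based with shared boundaries
(the printed annotation style of the source corpora); in-memory label
sequences are ordinary 0-based arrays.  A shared boundary sample belongs to
the LATER region, and the final row additionally claims its own end sample,
so a table ending at limit N expands to exactly N labels.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile

#: Cardiac phase classes in their cyclic (and encoding) order.
CLASSES: tuple[str, ...] = ("S1", "systolic", "S2", "diastolic")
CLASS_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}

#: Recognised auscultation sites (aortic, pulmonic, tricuspid, mitral).
SITES: tuple[str, ...] = ("AV", "PV", "TV", "MV", "other", "unknown")


class FormatError(ValueError):
    """An input file violates the expected container or encoding."""


class ValidationError(ValueError):
    """A region table or label sequence violates its invariants."""


def _next_phase(cls: str) -> str:
    return CLASSES[(CLASS_TO_INDEX[cls] + 1) % len(CLASSES)]


@dataclass(frozen=True)
class PcgRecord:
    """A mono heart-sound recording."""

    record_id: str
    samples: np.ndarray
    sampling_rate_hz: int
    site: str = "unknown"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples contain non-finite values")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.site not in SITES:
            raise ValidationError(
                f"unknown site {self.site!r}; expected one of {SITES}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class RegionTable:
    """Ordered (start, end, class) annotation rows over 1-based sample indices."""

    rows: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(tuple(r) for r in self.rows))
        self.validate()

    def validate(self) -> None:
        if not self.rows:
            raise ValidationError("region table has no rows")
        prev_end = None
        prev_cls = None
        for k, (start, end, cls) in enumerate(self.rows, start=1):
            if cls not in CLASS_TO_INDEX:
                raise ValidationError(
                    f"row {k}: unknown class {cls!r}; expected one of {CLASSES}"
                )
            if start >= end:
                raise ValidationError(f"row {k}: start {start} >= end {end}")
            if start < 1:
                raise ValidationError(f"row {k}: start {start} < 1")
            if prev_end is not None:
                if start > prev_end:
                    raise ValidationError(
                        f"row {k}: gap between previous end {prev_end} and start {start}"
                    )
                if start < prev_end:
                    raise ValidationError(
                        f"row {k}: overlap; start {start} precedes previous end {prev_end}"
                    )
                if cls != _next_phase(prev_cls):
                    raise ValidationError(
                        f"row {k}: class {cls!r} breaks the cyclic phase order "
                        f"(expected {_next_phase(prev_cls)!r} after {prev_cls!r})"
                    )
            prev_end, prev_cls = end, cls

    @property
    def n_samples(self) -> int:
        """Number of samples covered: the final end limit."""
        return self.rows[-1][1]


@dataclass(frozen=True)
class LabelSequence:
    """One cardiac-phase label per signal sample."""

    labels: np.ndarray  # int codes into CLASSES
    sampling_rate_hz: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1 or labels.size == 0:
            raise ValidationError("labels must be a non-empty 1-D sequence")
        if labels.min() < 0 or labels.max() >= len(CLASSES):
            raise ValidationError("label codes out of range")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return self.labels.size

    def class_names(self) -> list[str]:
        return [CLASSES[i] for i in self.labels]


@dataclass
class SegmentDataset:
    """Fixed-length (feature window, label window) pairs ready for a model.

    Per-segment metadata (``source_ids``, ``sites``) lets evaluation group
    results by record or auscultation site and lets training split by
    source record rather than by window.
    """

    features: np.ndarray  # (n_segments, window_len) float
    labels: np.ndarray  # (n_segments, window_len) int codes
    source_ids: list[str]
    sampling_rate_hz: int
    window_seconds: float = 2.0
    sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.shape != self.labels.shape:
            raise ValidationError("features and labels must have equal shape")
        if self.features.ndim != 2:
            raise ValidationError("expected (n_segments, window_len) arrays")
        if self.features.size and not np.all(np.isfinite(self.features)):
            raise ValidationError("features contain non-finite values")
        if len(self.source_ids) != self.features.shape[0]:
            raise ValidationError("source_ids must have one entry per segment")
        if not self.sites:
            self.sites = ["unknown"] * self.features.shape[0]
        if len(self.sites) != self.features.shape[0]:
            raise ValidationError("sites must have one entry per segment")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def window_len(self) -> int:
        return self.features.shape[1]

    @staticmethod
    def concatenate(parts: Iterable["SegmentDataset"]) -> "SegmentDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValidationError("nothing to concatenate")
        rate = parts[0].sampling_rate_hz
        wsec = parts[0].window_seconds
        for p in parts:
            if p.sampling_rate_hz != rate or p.window_len != parts[0].window_len:
                raise ValidationError("cannot concatenate datasets of unequal geometry")
        return SegmentDataset(
            features=np.concatenate([p.features for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            source_ids=[i for p in parts for i in p.source_ids],
            sampling_rate_hz=rate,
            window_seconds=wsec,
            sites=[s for p in parts for s in p.sites],
        )

    def subset(self, idx: Sequence[int]) -> "SegmentDataset":
        idx = np.asarray(idx, dtype=int)
        return SegmentDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            source_ids=[self.source_ids[i] for i in idx],
            sampling_rate_hz=self.sampling_rate_hz,
            window_seconds=self.window_seconds,
            sites=[self.sites[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# WAV input/output


def read_record(path: str | Path, site: str = "unknown") -> PcgRecord:
    """Read a mono WAV file (PCM or IEEE float) into a :class:`PcgRecord`.

    Integer PCM samples are rescaled to [-1, 1]; float data is taken as-is.
    Multi-channel audio is rejected.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises ValueError on malformed WAV
        raise FormatError(f"{path}: unreadable or unsupported WAV file: {exc}") from exc
    if data.ndim != 1:
        raise FormatError(
            f"{path}: expected mono audio, got {data.shape[1]}-channel WAV"
        )
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        samples = data.astype(float) / scale
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        raise FormatError(f"{path}: unsupported WAV encoding {data.dtype}")
    return PcgRecord(
        record_id=path.stem, samples=samples, sampling_rate_hz=int(rate), site=site
    )


def write_record(path: str | Path, rec: PcgRecord) -> None:
    """Write a record as a 32-bit IEEE-float WAV (lossless for our purposes)."""
    wavfile.write(Path(path), rec.sampling_rate_hz, rec.samples.astype(np.float32))


# ---------------------------------------------------------------------------
# Region tables


def read_region_table(path: str | Path) -> RegionTable:
    """Parse a delimited three-column (start, end, class) annotation file.

    Accepts tab- or comma-delimited text, with or without a header row, and
    quoted or bare class names.  Invariant violations are reported with the
    offending row number.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValidationError(f"{path}: empty region-table file")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows: list[tuple[int, int, str]] = []
    for lineno, parts in enumerate(
        csv.reader(text.splitlines(), delimiter=delimiter), start=1
    ):
        parts = [p.strip().strip('"').strip("'") for p in parts if p.strip()]
        if not parts:
            continue
        if len(parts) != 3:
            raise ValidationError(
                f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
            )
        try:
            start, end = int(parts[0]), int(parts[1])
        except ValueError:
            if lineno == 1:  # tolerated header row
                continue
            raise ValidationError(
                f"{path}:{lineno}: non-integer region limits {parts[:2]}"
            ) from None
        rows.append((start, end, parts[2]))
    if not rows:
        raise ValidationError(f"{path}: no annotation rows found")
    try:
        return RegionTable(tuple(rows))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_region_table(path: str | Path, table: RegionTable) -> None:
    """Write a table in the same three-column tab-delimited form it is read from."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for start, end, cls in table.rows:
            writer.writerow([start, end, cls])


def expand_labels(table: RegionTable) -> LabelSequence:
    """Expand a region table to one label per sample.

    Sample ``n`` (1-based) receives the class of the row with the largest
    start <= n; the final row also claims its own end sample.  The result
    therefore has exactly ``table.n_samples`` entries, with each shared
    boundary sample belonging to the later region.
    """
    if table.rows[0][0] != 1:
        raise ValidationError(
            f"cannot expand a table whose first row starts at {table.rows[0][0]}, not 1"
        )
    n = table.n_samples
    labels = np.empty(n, dtype=np.int64)
    for k, (start, end, cls) in enumerate(table.rows):
        last = end if k == len(table.rows) - 1 else end - 1
        labels[start - 1 : last] = CLASS_TO_INDEX[cls]
    return LabelSequence(labels=labels, sampling_rate_hz=1)


def expand_labels_at_rate(table: RegionTable, rate: int) -> LabelSequence:
    seq = expand_labels(table)
    return LabelSequence(labels=seq.labels, sampling_rate_hz=rate)


def collapse_labels(seq: LabelSequence) -> RegionTable:
    """Run-length encode a label sequence back into a region table.

    Inverse of :func:`expand_labels` for every valid table.  A sequence whose
    runs break the cyclic phase order is still encoded faithfully; the order
    violation is reported as a warning rather than an error.
    """
    codes = seq.labels
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))  # 0-based run starts
    ends = np.concatenate((change, [codes.size]))  # 0-based exclusive
    rows = []
    for k, (a, b) in enumerate(zip(starts, ends)):
        # 1-based shared-boundary limits: interior rows end where the next starts
        end_limit = int(b) if k == len(starts) - 1 else int(b) + 1
        rows.append((int(a) + 1, end_limit, CLASSES[codes[a]]))
    ordered = all(
        rows[k + 1][2] == _next_phase(rows[k][2]) for k in range(len(rows) - 1)
    )
    if not ordered:
        warnings.warn(
            "collapsed label runs do not follow the cyclic phase order",
            stacklevel=2,
        )
        table = RegionTable.__new__(RegionTable)
        object.__setattr__(table, "rows", tuple(rows))
        return table
    return RegionTable(tuple(rows))


# ---------------------------------------------------------------------------
# Windowing


def segment_record(
    features: np.ndarray,
    labels: LabelSequence,
    window_seconds: float,
    rate: int,
    record_id: str = "record",
    site: str = "unknown",
) -> SegmentDataset:
    """Cut a feature/label pair into consecutive non-overlapping windows.

    Windows are ``round(window_seconds * rate)`` samples long; a trailing
    remainder shorter than one window is dropped.  A record shorter than one
    window yields an empty dataset with a warning.
    """
    features = np.asarray(features, dtype=float)
    if features.size != len(labels):
        raise ValidationError(
            f"features ({features.size}) and labels ({len(labels)}) differ in length"
        )
    wlen = int(round(window_seconds * rate))
    if wlen <= 0:
        raise ValidationError("window length rounds to zero samples")
    n_windows = features.size // wlen
    if n_windows == 0:
        warnings.warn(
            f"record {record_id!r} ({features.size} samples) is shorter than one "
            f"{wlen}-sample window; dataset is empty",
            stacklevel=2,
        )
    used = n_windows * wlen
    return SegmentDataset(
        features=features[:used].reshape(n_windows, wlen),
        labels=labels.labels[:used].reshape(n_windows, wlen),
        source_ids=[record_id] * n_windows,
        sampling_rate_hz=rate,
        window_seconds=window_seconds,
        sites=[site] * n_windows,
    )
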