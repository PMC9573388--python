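"""WFDB ingestion and AAMI beat-class mapping (optional real-data path).

Implements a minimal reader/writer for the WFDB interchange formats the
MIT-BIH arrhythmia records use: text headers (``.hea``), signal files in
format 16 (little-endian int16) and format 212 (packed 12-bit pairs),
and the MIT binary annotation format (``.atr``).  Only what the beat
pipeline needs is supported — single-segment records, one annotator,
beat-level symbols.

Beat symbols are aggregated to the four modeled AAMI super-classes:
NB <- {N, L, R, e, j}, SVEB <- {A, a, J, S}, VEB <- {V, E}, FB <- {F};
everything else (paced, unclassifiable — the "unknown" group) is dropped
and counted.  Records 102, 104, 107 and 217 contain paced rhythms and
are excluded wholesale.
"""

from __future__ import annotations

import os
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cwt import compute_cwt_batch, make_scales, scalogram_array
from .preprocess import (
    EcgRecord,
    SegmentationConfig,
    remove_baseline,
    segment_heartbeats,
)
from .train_eval import AAMI_CLASSES, Dataset

__all__ = [
    "AamiMapping",
    "DEFAULT_MAPPING",
    "map_symbol_to_aami",
    "load_record",
    "build_dataset",
    "read_wfdb",
    "write_wfdb",
    "read_annotations",
    "write_annotations",
]

# MIT annotation code <-> display symbol (beat codes plus common non-beat)
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    37: "x", 38: "f", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

#: symbols that annotate QRS complexes (everything else is rhythm/noise/etc.)
_BEAT_SYMBOLS = frozenset(
    {"N", "L", "R", "a", "V", "F", "J", "A", "S", "E", "j", "/", "Q", "e",
     "n", "f", "r", "B", "?"}
)

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass(frozen=True)
class AamiMapping:
    """Beat-symbol aggregation table plus record exclusions."""

    symbol_to_class: dict = field(default_factory=lambda: {
        "N": "NB", "L": "NB", "R": "NB", "e": "NB", "j": "NB",
        "A": "SVEB", "a": "SVEB", "J": "SVEB", "S": "SVEB",
        "V": "VEB", "E": "VEB",
        "F": "FB",
    })
    excluded_records: frozenset = frozenset({"102", "104", "107", "217"})

    def map(self, symbol: str) -> str | None:
        return self.symbol_to_class.get(symbol)


DEFAULT_MAPPING = AamiMapping()


def map_symbol_to_aami(symbol: str) -> str | None:
    """AAMI super-class for a beat symbol, or None if dropped."""
    return DEFAULT_MAPPING.map(symbol)


# ---------------------------------------------------------------------------
# header


@dataclass
class _SignalSpec:
    filename: str
    fmt: int
    gain: float
    baseline: int
    units: str
    adc_zero: int
    description: str


def _parse_header(path: Path):
    lines = [
        ln.strip() for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    nsamp = int(head[3]) if len(head) > 3 else 0
    specs = []
    for ln in lines[1 : 1 + nsig]:
        tok = ln.split()
        fmt = int(re.split(r"[x:+]", tok[1])[0])
        gain_field = tok[2]
        m = re.match(r"([-\d.]+)(?:\((-?\d+)\))?(?:/(\S+))?", gain_field)
        gain = float(m.group(1)) if m else 200.0
        if gain == 0:
            gain = 200.0
        baseline_tok = m.group(2) if m else None
        units = m.group(3) if m and m.group(3) else "mV"
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        baseline = int(baseline_tok) if baseline_tok is not None else adc_zero
        description = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(specs)}"
        specs.append(_SignalSpec(tok[0], fmt, gain, baseline, units,
                                 adc_zero, description))
    return name, nsig, fs, nsamp, specs


# ---------------------------------------------------------------------------
# signal data


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = (n_values + 1) // 2
    b = b[: 3 * n_pairs].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] >> 4) << 8) | b[:, 2]
    out = np.empty(2 * n_pairs, dtype=np.int32)
    out[0::2], out[1::2] = s0, s1
    out[out >= 2048] -= 4096
    return out[:n_values]


def _encode_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if v.size % 2:
        v = np.concatenate([v, [0]])
    v = np.where(v < 0, v + 4096, v)
    b = np.empty((v.size // 2, 3), dtype=np.uint8)
    s0, s1 = v[0::2], v[1::2]
    b[:, 0] = s0 & 0xFF
    b[:, 1] = ((s1 >> 8) << 4) | (s0 >> 8)
    b[:, 2] = s1 & 0xFF
    return b.tobytes()


def read_wfdb(path_prefix):
    """Read a WFDB record (header + signals) into physical units.

    Returns ``(signals, fs, leads)`` with signals shaped
    ``(n_samples, n_signals)`` in the header's physical units.
    """
    prefix = Path(path_prefix)
    name, nsig, fs, nsamp, specs = _parse_header(prefix.with_suffix(".hea"))
    by_file: dict[str, list[int]] = {}
    for k, spec in enumerate(specs):
        by_file.setdefault(spec.filename, []).append(k)
    signals = np.empty((nsamp, nsig))
    for fname, idxs in by_file.items():
        raw = (prefix.parent / fname).read_bytes()
        fmt = specs[idxs[0]].fmt
        n_values = nsamp * len(idxs)
        if fmt == 16:
            adc = np.frombuffer(raw, dtype="<i2", count=n_values).astype(np.int32)
        elif fmt == 212:
            adc = _decode_212(raw, n_values)
        else:
            raise ValueError(f"unsupported WFDB signal format {fmt}")
        adc = adc.reshape(nsamp, len(idxs))
        for col, k in enumerate(idxs):
            spec = specs[k]
            signals[:, k] = (adc[:, col] - spec.baseline) / spec.gain
    leads = [s.description for s in specs]
    return signals, fs, leads


def write_wfdb(path_prefix, signals, fs: float, leads, fmt: int = 16,
               gain: float = 200.0, units: str = "mV"):
    """Write signals (n_samples, n_signals) as a WFDB record."""
    prefix = Path(path_prefix)
    signals = np.asarray(signals, dtype=float)
    if signals.ndim == 1:
        signals = signals[:, None]
    if signals.ndim != 2 or signals.shape[0] < signals.shape[1]:
        raise ValueError("signals must be (n_samples, n_signals)")
    nsamp, nsig = signals.shape
    if len(leads) != nsig:
        raise ValueError("one lead name per signal required")
    adc = np.round(signals * gain).astype(np.int32)
    if fmt == 212 and np.any(np.abs(adc) > 2047):
        raise ValueError("format 212 cannot store values beyond 12 bits")
    name = prefix.name
    dat_name = f"{name}.dat"
    lines = [f"{name} {nsig} {fs:g} {nsamp}"]
    for k, lead in enumerate(leads):
        lines.append(f"{dat_name} {fmt} {gain:g}/{units} 12 0 0 0 0 {lead}")
    prefix.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    interleaved = adc.reshape(-1) if nsig == 1 else adc.reshape(nsamp * nsig)
    if fmt == 16:
        data = interleaved.astype("<i2").tobytes()
    elif fmt == 212:
        data = _encode_212(interleaved)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    (prefix.parent / dat_name).write_bytes(data)


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path) -> list[tuple[int, str]]:
    """Read an MIT-format annotation file into (sample_index, symbol)."""
    raw = Path(path).read_bytes()
    out: list[tuple[int, str]] = []
    time = 0
    pos = 0
    n = len(raw)
    while pos + 1 < n:
        word = struct.unpack_from("<H", raw, pos)[0]
        pos += 2
        code = word >> 10
        inc = word & 0x3FF
        if code == 0 and inc == 0:
            break
        if code == _SKIP:
            hi, lo = struct.unpack_from("<HH", raw, pos)
            pos += 4
            time += (hi << 16) | lo
        elif code == _AUX:
            pos += inc + (inc & 1)  # aux string, padded to even length
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            time += inc
            out.append((time, _CODE_TO_SYMBOL.get(code, "Q")))
    return out


def write_annotations(path, annotations) -> None:
    """Write (sample_index, symbol) pairs in MIT annotation format."""
    words = bytearray()
    prev = 0
    for idx, sym in sorted(annotations):
        delta = idx - prev
        if delta < 0:
            raise ValueError("annotation indices must be non-decreasing")
        if delta > 1023:
            words += struct.pack("<H", _SKIP << 10)
            words += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        code = _SYMBOL_TO_CODE.get(sym, 13)
        words += struct.pack("<H", (code << 10) | delta)
        prev = idx
    words += struct.pack("<H", 0)
    Path(path).write_bytes(bytes(words))


# ---------------------------------------------------------------------------
# record-level API


def load_record(path_prefix, lead: str = "MLII") -> EcgRecord:
    """Load one WFDB record, selecting a lead by name.

    Annotations are filtered to beat symbols only.  Lead selection is by
    header description (not channel index) because some records store
    the modified limb lead second.
    """
    prefix = Path(path_prefix)
    signals, fs, leads = read_wfdb(prefix)
    if lead not in leads:
        raise ValueError(
            f"record {prefix.name!r} has no lead {lead!r}; "
            f"available: {', '.join(leads)}"
        )
    atr = prefix.with_suffix(".atr")
    if not atr.exists():
        raise FileNotFoundError(f"annotation file not found: {atr}")
    anns = [
        (idx, sym) for idx, sym in read_annotations(atr)
        if sym in _BEAT_SYMBOLS and 0 <= idx < signals.shape[0]
    ]
    return EcgRecord(
        record_id=prefix.name,
        samples=signals[:, leads.index(lead)],
        fs=fs, lead=lead, annotations=anns,
    )


def build_dataset(
    record_dir,
    mapping: AamiMapping | None = None,
    seg_cfg: SegmentationConfig | None = None,
    lead: str = "MLII",
    wavelet: str = "gaus8",
    n_scales: int = 100,
    scale_lo: float = 2.16,
    scale_hi: float = 216.0,
    image_shape: tuple[int, int] = (100, 100),
):
    """Full pipeline over a directory of WFDB records.

    Excluded records are skipped; remaining records are denoised,
    segmented at their annotated R-peaks, label-mapped to AAMI classes
    (unmapped symbols dropped and counted) and scalogram-transformed.
    Returns ``(dataset, report)`` where the report carries per-class
    counts, dropped-symbol counts and the records processed/skipped.
    """
    mapping = mapping or DEFAULT_MAPPING
    seg_cfg = seg_cfg or SegmentationConfig()
    record_dir = Path(record_dir)
    prefixes = sorted(p.with_suffix("") for p in record_dir.glob("*.hea"))
    if not prefixes:
        raise ValueError(f"no WFDB records found in {record_dir}")
    class_to_idx = {c: i for i, c in enumerate(AAMI_CLASSES)}
    beats, labels = [], []
    report = {
        "processed": [], "skipped": [], "dropped_symbols": 0,
        "dropped_boundary": 0, "class_counts": dict.fromkeys(AAMI_CLASSES, 0),
    }
    fs = None
    for prefix in prefixes:
        if prefix.name in mapping.excluded_records:
            report["skipped"].append(prefix.name)
            continue
        record = load_record(prefix, lead=lead)
        fs = record.fs
        denoised = remove_baseline(record)
        result = segment_heartbeats(denoised, seg_cfg)
        report["dropped_boundary"] += result.n_dropped
        for seg in result.segments:
            cls = mapping.map(seg.label)
            if cls is None:
                report["dropped_symbols"] += 1
                continue
            beats.append(seg.samples)
            labels.append(class_to_idx[cls])
            report["class_counts"][cls] += 1
        report["processed"].append(prefix.name)
    if not beats:
        raise ValueError(f"no mappable beats found in {record_dir}")
    beats = np.stack(beats)
    labels = np.asarray(labels)
    grid = make_scales(n_scales, scale_lo, scale_hi)
    coeffs = compute_cwt_batch(beats, grid, wavelet, fs)
    scalograms = np.stack([
        scalogram_array(np.abs(c), image_shape) for c in coeffs
    ])
    dataset = Dataset(beats=beats, scalograms=scalograms, labels=labels,
                      class_names=AAMI_CLASSES)
    return dataset, report
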