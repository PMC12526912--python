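"""Record IO: WFDB files, the MIT-BIH → AAMI symbol map, JSON stream chunks.

The reader/writer here covers the subset of the WFDB standard the pipeline
needs — single- or multi-lead format-16 signal files with plain headers and
MIT-format binary annotation files — and is exercised by write→read round
trips.  Physical units are millivolts throughout: samples are stored as
``adc = round(x * gain) + baseline`` and recovered as
``(adc - baseline) / gain``.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

AAMI_CLASSES = ("N", "S", "V", "F", "Q")

#: MIT-BIH beat symbols grouped by AAMI class
_AAMI_GROUPS = {
    "N": ("N", "L", "R", "e", "j"),
    "S": ("A", "a", "J", "S"),
    "V": ("V", "E"),
    "F": ("F",),
    "Q": ("/", "f", "Q"),
}
_SYMBOL_TO_AAMI = {sym: cls for cls, syms in _AAMI_GROUPS.items() for sym in syms}

#: records dominated by paced rhythms, excluded from training
DEFAULT_EXCLUDE = ("102", "104", "107", "217")

# MIT annotation code <-> symbol table (beat and non-beat codes)
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


class RecordIOError(IOError):
    """Missing or malformed WFDB files."""


class SchemaError(ValueError):
    """Malformed JSON stream message."""

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"stream chunk is missing field {field!r}")


@dataclass
class EcgRecord:
    """A single selected lead of one recording, in physical units (mV)."""

    record_id: str
    signal: np.ndarray
    fs: float
    lead_name: str = "MLII"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise RecordIOError("sampling frequency must be positive")
        self.signal = np.asarray(self.signal, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.signal)


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated event: sample index, raw symbol, derived AAMI class.

    ``aami_class`` is ``None`` for non-beat symbols (rhythm changes,
    quality marks) and for beat symbols outside the five AAMI groups.
    """

    sample_index: int
    symbol: str
    aami_class: str | None

    @classmethod
    def from_symbol(cls, sample_index: int, symbol: str) -> "BeatAnnotation":
        return cls(sample_index, symbol, map_to_aami(symbol))


def map_to_aami(symbol: str) -> str | None:
    """Map a single MIT-BIH annotation symbol to its AAMI class, else None."""
    if not isinstance(symbol, str) or len(symbol) != 1:
        raise ValueError("annotation symbol must be a single character")
    return _SYMBOL_TO_AAMI.get(symbol)


# ---------------------------------------------------------------------------
# WFDB signal files (format 16)
# ---------------------------------------------------------------------------

def write_record(
    path_base: str | Path,
    signals: np.ndarray,
    fs: float,
    lead_names: list[str] | None = None,
    gain: float = 200.0,
    baseline: int = 0,
) -> None:
    """Write ``signals`` (n_samples or n_samples×n_leads, mV) as a WFDB
    format-16 record ``<path_base>.hea`` + ``<path_base>.dat``."""
    path_base = Path(path_base)
    sig = np.asarray(signals, dtype=float)
    if sig.ndim == 1:
        sig = sig[:, None]
    n_samples, n_leads = sig.shape
    lead_names = lead_names or [f"lead{i}" if i else "MLII" for i in range(n_leads)]

    adc = np.clip(np.round(sig * gain) + baseline, -32768, 32767).astype("<i2")
    path_base.parent.mkdir(parents=True, exist_ok=True)
    with open(path_base.with_suffix(".dat"), "wb") as fh:
        fh.write(adc.reshape(-1).tobytes())  # interleaved by sample

    lines = [f"{path_base.name} {n_leads} {fs:g} {n_samples}"]
    for j in range(n_leads):
        first = int(adc[0, j])
        checksum = int(np.sum(adc[:, j], dtype=np.int64) % 65536)
        lines.append(
            f"{path_base.name}.dat 16 {gain:g}({baseline})/mV 16 0 "
            f"{first} {checksum} 0 {lead_names[j]}"
        )
    path_base.with_suffix(".hea").write_text("\n".join(lines) + "\n")


def _parse_gain(token: str) -> tuple[float, int | None]:
    """Parse a header gain token like ``200``, ``200/mV`` or ``200(0)/mV``."""
    token = token.split("/")[0]
    baseline = None
    if "(" in token:
        token, rest = token.split("(")
        baseline = int(rest.rstrip(")"))
    gain = float(token) if token else 200.0
    return (gain if gain != 0 else 200.0), baseline


def read_record(path_base: str | Path, lead: str | int = 0) -> EcgRecord:
    """Read one lead of a WFDB format-16 record in physical units (mV)."""
    path_base = Path(path_base)
    hea = path_base.with_suffix(".hea")
    if not hea.exists():
        raise RecordIOError(f"no header file {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_leads = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0

    specs = []
    for ln in lines[1:1 + n_leads]:
        parts = ln.split()
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = _parse_gain(parts[2]) if len(parts) > 2 else (200.0, None)
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        name = parts[8] if len(parts) > 8 else f"lead{len(specs)}"
        specs.append({
            "file": parts[0], "fmt": fmt, "gain": gain,
            "baseline": baseline if baseline is not None else adc_zero,
            "name": name,
        })

    if isinstance(lead, int):
        if not 0 <= lead < n_leads:
            raise RecordIOError(
                f"lead index {lead} out of range; record has {n_leads} leads")
        idx = lead
    else:
        names = [s["name"] for s in specs]
        if lead not in names:
            raise RecordIOError(f"lead {lead!r} not present; available: {names}")
        idx = names.index(lead)

    if any(s["fmt"] != "16" for s in specs):
        raise RecordIOError("only format-16 signal files are supported")
    dat = path_base.parent / specs[idx]["file"]
    if not dat.exists():
        raise RecordIOError(f"no signal file {dat}")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if n_samples:
        raw = raw[: n_samples * n_leads]
    adc = raw.reshape(-1, n_leads)[:, idx].astype(float)
    physical = (adc - specs[idx]["baseline"]) / specs[idx]["gain"]
    return EcgRecord(path_base.name, physical, fs, specs[idx]["name"])


# ---------------------------------------------------------------------------
# MIT-format annotation files
# ---------------------------------------------------------------------------

def write_annotations(
    path: str | Path, samples: np.ndarray, symbols: list[str]
) -> None:
    """Write annotations as a MIT-format file (typically ``<record>.atr``)."""
    if len(samples) != len(symbols):
        raise RecordIOError("samples/symbols length mismatch")
    out = bytearray()
    prev = 0
    for s, sym in zip(samples, symbols):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise RecordIOError(f"symbol {sym!r} has no MIT annotation code")
        delta = int(s) - prev
        if delta < 0:
            raise RecordIOError("annotation samples must be non-decreasing")
        if delta > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        prev = int(s)
    out += struct.pack("<H", 0)  # EOF
    Path(path).write_bytes(bytes(out))


def read_annotations(path: str | Path) -> list[BeatAnnotation]:
    """Read a MIT-format annotation file into BeatAnnotations."""
    path = Path(path)
    if not path.exists():
        raise RecordIOError(f"no annotation file {path}")
    buf = path.read_bytes()
    anns: list[BeatAnnotation] = []
    t = 0
    pos = 0
    pending_skip = 0
    while pos + 2 <= len(buf):
        (word,) = struct.unpack_from("<H", buf, pos)
        pos += 2
        code, interval = word >> 10, word & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            hi, lo = struct.unpack_from("<HH", buf, pos)
            pos += 4
            pending_skip += (hi << 16) | lo
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            pos += interval + (interval % 2)
            continue
        t += interval + pending_skip
        pending_skip = 0
        sym = _CODE_TO_SYMBOL.get(code)
        if sym is not None:
            anns.append(BeatAnnotation.from_symbol(t, sym))
    return anns


def load_dataset(
    root: str | Path,
    exclude: tuple[str, ...] | list[str] = DEFAULT_EXCLUDE,
    lead: str | int = 0,
) -> list[tuple[EcgRecord, list[BeatAnnotation]]]:
    """Load every WFDB record under ``root`` except the excluded ids.

    The default exclusion list removes the four paced-rhythm recordings
    (102, 104, 107, 217); on a full MIT-BIH directory this leaves 44 of
    the 48 records.
    """
    root = Path(root)
    headers = sorted(root.glob("*.hea"))
    if not headers:
        raise RecordIOError(f"no WFDB records found under {root}")
    excluded = {str(e) for e in exclude}
    out = []
    for hea in headers:
        rec_id = hea.stem
        if rec_id in excluded:
            continue
        record = read_record(hea.with_suffix(""), lead=lead)
        atr = hea.with_suffix(".atr")
        anns = read_annotations(atr) if atr.exists() else []
        out.append((record, anns))
    return out


# ---------------------------------------------------------------------------
# JSON stream dialect
# ---------------------------------------------------------------------------

@dataclass
class StreamChunk:
    """One JSON message of streamed samples at the source rate."""

    timestamp_ms: int
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise SchemaError("samples", "stream chunk has no samples")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StreamChunk):
            return NotImplemented
        return (
            self.timestamp_ms == other.timestamp_ms
            and self.fs == other.fs
            and np.array_equal(self.samples, other.samples)
        )


def encode_chunk(chunk: StreamChunk) -> str:
    """Serialize a chunk to JSON text with full float precision."""
    return json.dumps({
        "timestamp_ms": int(chunk.timestamp_ms),
        "fs": chunk.fs,
        "samples": [float(v) for v in chunk.samples],
    })


def decode_chunk(text: str) -> StreamChunk:
    """Parse JSON text into a StreamChunk, naming any missing field."""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError("<json>", f"malformed JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise SchemaError("<json>", "stream chunk must be a JSON object")
    for key in ("timestamp_ms", "fs", "samples"):
        if key not in obj:
            raise SchemaError(key)
    if not isinstance(obj["samples"], list) or not obj["samples"]:
        raise SchemaError("samples", "samples must be a non-empty array")
    return StreamChunk(int(obj["timestamp_ms"]), float(obj["fs"]),
                       np.asarray(obj["samples"], dtype=float))
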