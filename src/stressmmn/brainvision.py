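"""Minimal BrainVision (.vhdr / .vmrk / .eeg) reader and writer.

Supports the dialect the pipeline itself produces and the common recorder
output: INI-style header, binary IEEE float32 or int16 (with per-channel
resolution scaling) data in multiplexed orientation, microvolt units.
Vectorized orientation and other binary formats raise an explicit
unsupported-dialect error.  Marker positions follow the format's 1-based
data-point convention; stimulus markers "S 1".."S 7" map to the standard
and the six deviant types in the fixed documented order.
"""

from __future__ import annotations

import configparser
import os
import re

import numpy as np

from .eegsim import Recording
from .errors import DataError
from .paradigm import CODE_LABELS, MARKER_CODES

_SUPPORTED_FORMATS = {"IEEE_FLOAT_32": np.float32, "INT_16": np.int16}


def write_brainvision(
    rec: Recording,
    basepath: str,
    binary_format: str = "IEEE_FLOAT_32",
    resolution_uv: float = 0.1,
) -> None:
    """Write ``<basepath>.vhdr/.vmrk/.eeg`` (multiplexed, microvolts).

    ``resolution_uv`` is the quantization step used for INT_16 output and
    ignored for float32.
    """
    if binary_format not in _SUPPORTED_FORMATS:
        raise DataError(f"unsupported binary format {binary_format!r}")
    base = os.path.basename(basepath)
    n_ch = len(rec.ch_names)

    header = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={base}.eeg",
        f"MarkerFile={base}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / rec.sfreq:g}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    res = resolution_uv if binary_format == "INT_16" else 1.0
    for i, ch in enumerate(rec.ch_names):
        header.append(f"Ch{i + 1}={ch},,{res:g},µV")
    with open(basepath + ".vhdr", "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")

    marker_lines = [
        "BrainVision Data Exchange Marker File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={base}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for i, (label, sample) in enumerate(rec.markers):
        code = MARKER_CODES.get(label)
        desc = f"S {code}" if code is not None else label
        marker_lines.append(f"Mk{i + 2}=Stimulus,{desc},{sample + 1},1,0")
    with open(basepath + ".vmrk", "w", encoding="utf-8") as fh:
        fh.write("\n".join(marker_lines) + "\n")

    multiplexed = rec.data.T  # [samples x channels]
    if binary_format == "IEEE_FLOAT_32":
        multiplexed.astype(np.float32).tofile(basepath + ".eeg")
    else:
        quantized = np.round(multiplexed / resolution_uv)
        if np.abs(quantized).max(initial=0) > 32767:
            raise DataError("data exceed INT_16 range at this resolution")
        quantized.astype(np.int16).tofile(basepath + ".eeg")


def _read_ini(path: str) -> configparser.ConfigParser:
    parser = configparser.ConfigParser(interpolation=None, strict=True)
    parser.optionxform = str  # keep key case
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body = []
    in_section = False
    for line in lines:
        if line.startswith("["):
            in_section = True
        if in_section and not line.startswith(";"):
            body.append(line)
    parser.read_string("\n".join(body))
    return parser


def read_brainvision(vhdr_path: str) -> Recording:
    """Read a BrainVision triplet into a microvolt :class:`Recording`."""
    if not os.path.exists(vhdr_path):
        raise DataError(f"no such header file: {vhdr_path}")
    parser = _read_ini(vhdr_path)
    common = parser["Common Infos"]
    if common.get("DataFormat", "BINARY") != "BINARY":
        raise DataError("unsupported dialect: only BINARY DataFormat is handled")
    orientation = common.get("DataOrientation", "MULTIPLEXED")
    if orientation != "MULTIPLEXED":
        raise DataError(f"unsupported dialect: orientation {orientation!r}")
    fmt = parser["Binary Infos"].get("BinaryFormat", "")
    if fmt not in _SUPPORTED_FORMATS:
        raise DataError(f"unsupported dialect: binary format {fmt!r}")
    n_ch = int(common["NumberOfChannels"])
    sfreq = 1e6 / float(common["SamplingInterval"])

    ch_names, resolutions = [], []
    for i in range(n_ch):
        entry = parser["Channel Infos"][f"Ch{i + 1}"]
        parts = entry.split(",")
        ch_names.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    folder = os.path.dirname(os.path.abspath(vhdr_path))
    data_path = os.path.join(folder, common["DataFile"])
    raw = np.fromfile(data_path, dtype=_SUPPORTED_FORMATS[fmt])
    if raw.size % n_ch:
        raise DataError("data file length is not a multiple of the channel count")
    data = raw.reshape(-1, n_ch).T.astype(float)
    if fmt == "INT_16":
        data *= np.array(resolutions)[:, None]

    markers: list[tuple[str, int]] = []
    marker_path = os.path.join(folder, common.get("MarkerFile", ""))
    if common.get("MarkerFile") and os.path.exists(marker_path):
        mparser = _read_ini(marker_path)
        if "Marker Infos" in mparser:
            for key in sorted(
                mparser["Marker Infos"], key=lambda k: int(re.sub(r"\D", "", k) or 0)
            ):
                parts = mparser["Marker Infos"][key].split(",")
                if parts[0] != "Stimulus":
                    continue
                desc, position = parts[1], int(parts[2]) - 1
                m = re.fullmatch(r"S\s*(\d+)", desc)
                label = CODE_LABELS.get(int(m.group(1)), desc) if m else desc
                markers.append((label, position))
    return Recording(tuple(ch_names), sfreq, data, markers)
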