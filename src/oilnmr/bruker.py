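"""Reading and writing 1D NMR datasets in Bruker directory layout.

A dataset is a directory holding a binary ``fid`` file (interleaved
real/imaginary integers of the free induction decay) and an ``acqus``
parameter file in the JCAMP-DX-like ``##$KEY= value`` convention.  An
optional ``pdata/1/title`` sidecar names the sample.  Only 1D data are
supported; processed-data files (``1r``/``1i``) are not read.

Synthetic datasets written by :func:`write_bruker_dataset` use the same
layout (with zero group delay) so that simulated and instrument data enter
the pipeline identically.  Written data carry an ``##$NC=`` scaling
exponent so the integer quantization round-trips to high relative
precision; real instrument files without the key are read with unit scale.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "AcquisitionParameters",
    "RawFID",
    "DatasetError",
    "NotADatasetError",
    "read_acqus",
    "read_fid",
    "read_dataset",
    "write_bruker_dataset",
    "discover_datasets",
]

DEFAULT_TEMPERATURE_C = 30.0


class DatasetError(ValueError):
    """A dataset is present but malformed or inconsistent."""


class NotADatasetError(DatasetError):
    """The path does not contain an NMR dataset."""


@dataclass
class AcquisitionParameters:
    """Spectrometer and pulse-sequence metadata for a 1D acquisition.

    Defaults reproduce the screening protocol: a 300 MHz instrument, 12 ppm
    spectral width centred at 5 ppm, 16384 complex points (TD = 32768 stored
    reals), 8 scans plus 2 dummy scans, 4 s recycle delay, 30 deg C.
    """

    spectrometer_frequency: float = 300.13  # MHz
    spectral_width: float = 12.0  # ppm
    transmitter_offset: float = 5.0  # ppm
    n_complex_points: int = 16384
    n_scans: int = 8
    n_dummy_scans: int = 2
    acquisition_time: float = 4.56  # s (AQ)
    recycle_delay: float = 4.0  # s (D1)
    temperature: float = DEFAULT_TEMPERATURE_C  # deg C
    byte_order: str = "little"  # BYTORDA 0 = little, 1 = big
    data_type: str = "int32"  # DTYPA 0 = int32, 2 = float64
    group_delay: float = 0.0  # GRPDLY, complex points
    scale_exponent: int = 0  # NC: stored integers are value * 2**-NC

    def __post_init__(self) -> None:
        if self.spectral_width <= 0:
            raise DatasetError("spectral_width must be positive")
        if self.n_complex_points <= 0:
            raise DatasetError("n_complex_points must be positive")
        if self.n_scans < 1:
            raise DatasetError("n_scans must be >= 1")
        if not 0.0 <= self.temperature <= 80.0:
            raise DatasetError(
                f"temperature {self.temperature} degC outside the supported 0-80 degC range"
            )
        expected_aq = self.n_complex_points / self.spectral_width_hz
        if self.acquisition_time > 0 and abs(self.acquisition_time - expected_aq) > 0.05 * expected_aq:
            log.warning(
                "acquisition_time %.3f s deviates >5%% from TD/(2*SW) = %.3f s",
                self.acquisition_time,
                expected_aq,
            )

    @property
    def spectral_width_hz(self) -> float:
        return self.spectral_width * self.spectrometer_frequency

    @property
    def dwell_time(self) -> float:
        """Complex-point sampling interval in seconds."""
        return 1.0 / self.spectral_width_hz


@dataclass
class RawFID:
    """A complex time-domain NMR signal plus its acquisition metadata."""

    data: np.ndarray  # complex128, length n_complex_points
    params: AcquisitionParameters
    source_path: str = ""
    sample_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 1:
            raise DatasetError("FID must be one-dimensional")
        if len(self.data) != self.params.n_complex_points:
            raise DatasetError(
                f"FID length {len(self.data)} != n_complex_points "
                f"{self.params.n_complex_points}"
            )


# acqus parsing ---------------------------------------------------------------

_KEY_RE = re.compile(r"^##\$?([A-Za-z0-9_]+)=\s*(.*)$")

# JCAMP key -> (attribute, converter). SW_h/O1 handled separately.
_FLOAT_KEYS = {
    "SFO1": "spectrometer_frequency",
    "SW": "spectral_width",
    "D1": "recycle_delay",
    "AQ": "acquisition_time",
    "GRPDLY": "group_delay",
}
_INT_KEYS = {
    "NS": "n_scans",
    "DS": "n_dummy_scans",
    "NC": "scale_exponent",
}


def _parse_acqus_text(text: str) -> dict[str, str]:
    values: dict[str, str] = {}
    for line in text.splitlines():
        m = _KEY_RE.match(line.strip())
        if m:
            values[m.group(1)] = m.group(2).strip()
    return values


def read_acqus(path: str | Path) -> AcquisitionParameters:
    """Parse an ``acqus`` file in directory *path* into acquisition parameters.

    Missing optional keys take the documented defaults (e.g. temperature
    30 deg C when ``TE`` is absent, with a logged warning).  A directory
    without an ``acqus`` file raises :class:`NotADatasetError`.
    """
    path = Path(path)
    acqus = path / "acqus"
    if not acqus.is_file():
        raise NotADatasetError(f"not an NMR dataset: {path} has no acqus file")
    raw = _parse_acqus_text(acqus.read_text())

    def _num(key: str, cast):
        try:
            return cast(float(raw[key]))
        except (ValueError, TypeError) as exc:
            raise DatasetError(f"unparsable numeric field {key!r} in {acqus}") from exc

    kwargs: dict[str, object] = {}
    for key, attr in _FLOAT_KEYS.items():
        if key in raw:
            kwargs[attr] = _num(key, float)
    for key, attr in _INT_KEYS.items():
        if key in raw:
            kwargs[attr] = _num(key, int)

    sfo1 = float(kwargs.get("spectrometer_frequency", 300.13))
    if "SW" not in raw and "SW_h" in raw:
        kwargs["spectral_width"] = _num("SW_h", float) / sfo1
    if "O1" in raw:  # transmitter offset is stored in Hz
        kwargs["transmitter_offset"] = _num("O1", float) / sfo1
    if "TD" in raw:  # TD counts stored real values: 2 per complex point
        kwargs["n_complex_points"] = _num("TD", int) // 2
    if "TE" in raw:
        te = _num("TE", float)
        # Bruker stores TE in kelvin; tolerate Celsius in hand-written files.
        kwargs["temperature"] = te - 273.15 if te > 150.0 else te
    else:
        log.warning("acqus in %s lacks TE; defaulting temperature to 30 degC", path)
        kwargs["temperature"] = DEFAULT_TEMPERATURE_C
    if "BYTORDA" in raw:
        kwargs["byte_order"] = "big" if _num("BYTORDA", int) else "little"
    if "DTYPA" in raw:
        kwargs["data_type"] = "float64" if _num("DTYPA", int) == 2 else "int32"
    if "AQ" not in raw:
        sw_hz = float(kwargs.get("spectral_width", 12.0)) * sfo1
        kwargs["acquisition_time"] = int(kwargs.get("n_complex_points", 16384)) / sw_hz
    return AcquisitionParameters(**kwargs)


def read_fid(path: str | Path, params: AcquisitionParameters) -> RawFID:
    """Decode the binary ``fid`` file in *path* into a complex series.

    Interleaved real/imaginary values are read in the integer width and byte
    order announced by *params*; the digital-filter group delay (``GRPDLY``)
    is removed by dropping the leading points and zero-padding the tail so
    the length stays ``n_complex_points``.
    """
    path = Path(path)
    fid_file = path / "fid"
    if not fid_file.is_file():
        raise NotADatasetError(f"not an NMR dataset: {path} has no fid file")
    if params.data_type == "float64":
        dtype = "<f8" if params.byte_order == "little" else ">f8"
    else:
        dtype = "<i4" if params.byte_order == "little" else ">i4"
    values = np.fromfile(fid_file, dtype=dtype).astype(np.float64)
    expected = 2 * params.n_complex_points
    if len(values) != expected:
        raise DatasetError(
            f"fid size mismatch in {path}: expected {expected} stored values, "
            f"found {len(values)}"
        )
    data = (values[0::2] + 1j * values[1::2]) * 2.0 ** params.scale_exponent
    ngrp = int(round(params.group_delay))
    if ngrp > 0:
        data = np.concatenate([data[ngrp:], np.zeros(ngrp, dtype=np.complex128)])
    label = _read_title(path) or path.name
    return RawFID(data=data, params=params, source_path=str(path), sample_label=label)


def read_dataset(path: str | Path) -> RawFID:
    """Read ``acqus`` + ``fid`` from one dataset directory."""
    params = read_acqus(path)
    return read_fid(path, params)


def _read_title(path: Path) -> str:
    title = path / "pdata" / "1" / "title"
    if title.is_file():
        first = title.read_text().strip().splitlines()
        if first:
            return first[0].strip()
    return ""


# writing ---------------------------------------------------------------------

_ACQUS_TEMPLATE = """\
##TITLE= acquisition parameters
##JCAMPDX= 5.0
##DATATYPE= NMR FID
##ORIGIN= oilnmr synthetic dataset writer
##$BYTORDA= {bytorda}
##$DTYPA= 0
##$SFO1= {sfo1!r}
##$O1= {o1!r}
##$SW= {sw!r}
##$SW_h= {sw_h!r}
##$TD= {td}
##$NS= {ns}
##$DS= {ds}
##$D1= {d1!r}
##$AQ= {aq!r}
##$TE= {te!r}
##$GRPDLY= 0
##$DECIM= 1
##$NC= {nc}
##END=
"""


def write_bruker_dataset(
    fid: RawFID, path: str | Path, overwrite: bool = False
) -> Path:
    """Write *fid* as a Bruker-layout dataset under *path*.

    The complex series is quantized to 32-bit little-endian integers with a
    power-of-two scale recorded under ``##$NC=``, so ``read_fid`` recovers
    the series to within half a quantization step per point.  The sample
    label goes to ``pdata/1/title``.  Refuses to overwrite an existing
    dataset unless *overwrite* is set.
    """
    path = Path(path)
    if (path / "fid").exists() and not overwrite:
        raise DatasetError(f"dataset already exists at {path} (use overwrite=True)")
    path.mkdir(parents=True, exist_ok=True)

    data = fid.data
    peak = float(np.max(np.abs(np.concatenate([data.real, data.imag])))) if len(data) else 0.0
    # choose NC so that the largest magnitude maps near 2**29 (< int32 range)
    nc = int(math.ceil(math.log2(peak) - 29)) if peak > 0 else 0
    scaled = data * 2.0 ** (-nc)
    interleaved = np.empty(2 * len(data), dtype=np.float64)
    interleaved[0::2] = scaled.real
    interleaved[1::2] = scaled.imag
    ints = np.round(interleaved).astype("<i4")
    (path / "fid").write_bytes(ints.tobytes())

    p = fid.params
    (path / "acqus").write_text(
        _ACQUS_TEMPLATE.format(
            bytorda=0,
            sfo1=p.spectrometer_frequency,
            o1=p.transmitter_offset * p.spectrometer_frequency,
            sw=p.spectral_width,
            sw_h=p.spectral_width_hz,
            td=2 * p.n_complex_points,
            ns=p.n_scans,
            ds=p.n_dummy_scans,
            d1=p.recycle_delay,
            aq=p.acquisition_time,
            te=p.temperature + 273.15,
            nc=nc,
        )
    )
    title_dir = path / "pdata" / "1"
    title_dir.mkdir(parents=True, exist_ok=True)
    (title_dir / "title").write_text((fid.sample_label or path.name) + "\n")
    return path


def discover_datasets(root: str | Path) -> list[Path]:
    """Return all dataset directories below *root*, lexicographically sorted.

    A dataset directory is any directory containing both ``fid`` and
    ``acqus``.  Non-NMR folders are skipped; an empty root yields an empty
    list.  The ordering is deterministic across repeated calls.
    """
    root = Path(root)
    if not root.is_dir():
        return []
    hits = {
        p.parent
        for p in root.rglob("fid")
        if p.is_file() and (p.parent / "acqus").is_file()
    }
    if (root / "fid").is_file() and (root / "acqus").is_file():
        hits.add(root)
    return sorted(hits, key=lambda p: str(p))
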