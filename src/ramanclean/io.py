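"""Reading and writing plain-text spectrometer exports.

Confocal Raman instruments commonly export one measurement as a delimited
text table: the first column is the wavenumber axis (cm⁻¹) and each further
column is one CCD exposure ("frame"). The :class:`Dialect` descriptor covers
the layout variations seen in practice (delimiter, decimal mark, header
lines); the default is the most permissive: whitespace-delimited, axis
first, ``#`` comments skipped.

Axes are normalised to strictly ascending order internally; descending
exports are silently reversed (frames reordered consistently). All zone
intervals elsewhere in the package are closed in cm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AxisError, ParseError, StructureError, WriteError

__all__ = [
    "Dialect",
    "Spectrum",
    "FrameStack",
    "read_frames",
    "write_spectrum",
    "write_frames",
]

#: A degree-5 fit needs 6 points; one extra channel of margin.
MIN_CHANNELS = 7


@dataclass(frozen=True)
class Dialect:
    """Text-layout descriptor for an instrument export.

    Parameters
    ----------
    delimiter
        Column separator; ``None`` means any run of whitespace.
    decimal
        Decimal mark, ``"."`` or ``","``.
    header_lines
        Number of leading lines to skip unconditionally.
    comment
        Lines starting with this prefix are skipped anywhere in the file.
    """

    delimiter: str | None = None
    decimal: str = "."
    header_lines: int = 0
    comment: str = "#"


class Spectrum:
    """One wavenumber axis paired with one intensity vector.

    Invariants enforced at construction: axis strictly increasing, same
    length as intensities, at least :data:`MIN_CHANNELS` channels, all
    values finite.
    """

    __slots__ = ("wavenumbers", "intensities", "meta")

    def __init__(self, wavenumbers, intensities, meta: dict | None = None):
        w = np.asarray(wavenumbers, dtype=float)
        y = np.asarray(intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.shape != y.shape:
            raise AxisError("wavenumbers and intensities must be 1-D and equal length")
        if w.size < MIN_CHANNELS:
            raise AxisError(f"need at least {MIN_CHANNELS} channels, got {w.size}")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(y))):
            raise AxisError("non-finite values in spectrum")
        if not np.all(np.diff(w) > 0):
            raise AxisError("wavenumber axis must be strictly increasing")
        self.wavenumbers = w
        self.intensities = y
        self.meta = dict(meta) if meta else {}

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities, **meta_updates) -> "Spectrum":
        """Copy with new intensities on the same axis; meta merged."""
        m = {**self.meta, **{k: str(v) for k, v in meta_updates.items()}}
        return Spectrum(self.wavenumbers, intensities, m)


class FrameStack:
    """Several intensity frames sharing one wavenumber axis.

    ``frames`` is a 2-D array, one row per CCD exposure.
    """

    __slots__ = ("wavenumbers", "frames", "meta")

    def __init__(self, wavenumbers, frames, meta: dict | None = None):
        w = np.asarray(wavenumbers, dtype=float)
        f = np.asarray(frames, dtype=float)
        if f.ndim == 1:
            f = f[None, :]
        if w.ndim != 1 or f.ndim != 2:
            raise AxisError("axis must be 1-D and frames 2-D")
        if f.shape[0] < 1 or f.shape[1] != w.size:
            raise AxisError(
                f"frames shape {f.shape} incompatible with axis length {w.size}"
            )
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(f))):
            raise AxisError("non-finite values in frame stack")
        if not np.all(np.diff(w) > 0):
            raise AxisError("wavenumber axis must be strictly increasing")
        self.wavenumbers = w
        self.frames = f
        self.meta = dict(meta) if meta else {}

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size


def _parse_rows(path, dialect: Dialect):
    rows = []
    width = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if lineno <= dialect.header_lines:
                continue
            line = raw.strip()
            if not line or (dialect.comment and line.startswith(dialect.comment)):
                continue
            if dialect.decimal != ".":
                line = line.replace(dialect.decimal, ".")
            parts = line.split(dialect.delimiter)
            parts = [p for p in parts if p]  # collapse empty fields
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(lineno, f"cannot parse {raw.strip()!r}") from exc
            if width is None:
                width = len(values)
                if width < 2:
                    raise StructureError(
                        f"line {lineno}: need axis plus at least one frame column"
                    )
            elif len(values) != width:
                raise StructureError(
                    f"line {lineno}: expected {width} columns, got {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise StructureError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def read_frames(path, dialect: Dialect | None = None) -> FrameStack:
    """Read a multi-frame text export into a validated :class:`FrameStack`.

    Rows are sorted by wavenumber, so descending (or shuffled) exports are
    normalised to the ascending internal convention. Duplicate wavenumbers
    raise :class:`~ramanclean.errors.AxisError`.
    """
    dialect = dialect or Dialect()
    table = _parse_rows(path, dialect)
    order = np.argsort(table[:, 0], kind="stable")
    table = table[order]
    axis = table[:, 0]
    if np.any(np.diff(axis) <= 0):
        dupes = axis[:-1][np.diff(axis) <= 0]
        raise AxisError(f"duplicate wavenumber(s) {np.unique(dupes).tolist()}")
    stack = FrameStack(
        axis,
        table[:, 1:].T,
        meta={"source": str(path), "n_frames": str(table.shape[1] - 1)},
    )
    return stack


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a two-column (wavenumber, intensity) text file at full precision.

    ``read_frames`` on the result reproduces the spectrum to float
    representation precision.
    """
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in sorted(spectrum.meta.items()):
                fh.write(f"# {key}: {value}\n")
            for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
                fh.write(f"{float(w)!r}\t{float(y)!r}\n")
    except OSError as exc:
        raise WriteError(f"cannot write {path}: {exc}") from exc


def write_frames(stack: FrameStack, path) -> None:
    """Write a multi-column (axis + one column per frame) text file."""
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in sorted(stack.meta.items()):
                fh.write(f"# {key}: {value}\n")
            for i in range(stack.n_channels):
                cols = [float(stack.wavenumbers[i])] + [
                    float(v) for v in stack.frames[:, i]
                ]
                fh.write("\t".join(repr(c) for c in cols) + "\n")
    except OSError as exc:
        raise WriteError(f"cannot write {path}: {exc}") from exc
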