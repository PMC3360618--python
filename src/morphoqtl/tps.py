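"""TPS outline I/O and validation.

Outlines are digitized closed curves with exactly four homologous control
points (rostral midline, caudal midline, two maximal-width lateral points)
used for orientation and Procrustes normalization.  The TPS dialect read
here is the tpsDig family: an ``LM=k`` landmark block, an outline block
given either as ``CURVES=``/``POINTS=`` records or as a bare coordinate
list, and an ``ID=`` line per specimen.  Coordinates use the mathematical
convention (y up) and are assumed scale-calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: index of the rostral midline control point (the outline anchor)
CP_ROSTRAL = 0
#: index of the caudal midline control point
CP_CAUDAL = 1


class TPSFormatError(ValueError):
    """Malformed TPS input; message carries specimen and line context."""


@dataclass
class Outline:
    """A closed 2-D outline with four control points.

    Parameters
    ----------
    points
        ``(n, 2)`` array of outline vertices, ordered along the curve; the
        last point connects back to the first (not duplicated).
    control_points
        ``(4, 2)`` array: rostral midline, caudal midline, and the two
        maximal-width lateral points, in that order.
    specimen_id
        Free-text identifier.
    metadata
        Free key/value text carried through I/O.
    """

    points: np.ndarray
    control_points: np.ndarray
    specimen_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if self.points.shape[0] < 8:
            raise ValueError(
                f"outline '{self.specimen_id}': needs >= 8 points, "
                f"got {self.points.shape[0]}"
            )
        if self.control_points.shape != (4, 2):
            raise ValueError(
                f"outline '{self.specimen_id}': expected exactly 4 control "
                f"points, got {self.control_points.shape[0]}"
            )
        closed = np.vstack([self.points, self.points[:1]])
        if np.any(np.all(np.diff(closed, axis=0) == 0.0, axis=1)):
            raise ValueError(
                f"outline '{self.specimen_id}': consecutive identical points"
            )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def copy(self) -> "Outline":
        return Outline(
            self.points.copy(),
            self.control_points.copy(),
            self.specimen_id,
            dict(self.metadata),
        )


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def read_tps(source) -> list[Outline]:
    """Parse TPS text into a list of :class:`Outline`.

    ``source`` may be a path, an open text file, or a string of TPS text.
    Both ``CURVES=``/``POINTS=`` outline blocks and bare coordinate lists
    following the LM block are accepted.  Errors carry the specimen id and
    line number.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.strip() == "" or s.strip().upper().startswith("LM="):
            text = s
        else:
            with open(s) as fh:
                text = fh.read()

    lines = text.splitlines()
    outlines: list[Outline] = []
    i = 0
    n = len(lines)

    def parse_xy(line: str, lineno: int):
        parts = line.split()
        if len(parts) != 2:
            raise TPSFormatError(f"line {lineno}: expected 'x y', got {line!r}")
        try:
            return float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise TPSFormatError(f"line {lineno}: malformed number in {line!r}") from exc

    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSFormatError(f"line {i + 1}: expected LM= record, got {line!r}")
        rec_start = i + 1
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSFormatError(f"line {i + 1}: malformed LM count") from exc
        i += 1
        lm = []
        for _ in range(n_lm):
            if i >= n:
                raise TPSFormatError(f"line {i}: truncated LM block")
            lm.append(parse_xy(lines[i].strip(), i + 1))
            i += 1

        pts = []
        specimen_id = ""
        metadata: dict = {}
        n_curve_pts = None
        while i < n:
            line = lines[i].strip()
            up = line.upper()
            if up.startswith("LM="):
                break
            if up.startswith("CURVES="):
                i += 1
                continue
            if up.startswith("POINTS="):
                n_curve_pts = int(line.split("=", 1)[1])
                i += 1
                continue
            if up.startswith("ID="):
                specimen_id = line.split("=", 1)[1]
                i += 1
                continue
            if "=" in line and not line[0].isdigit() and not line[0] in "+-.":
                key, val = line.split("=", 1)
                metadata[key] = val
                i += 1
                continue
            if not line:
                i += 1
                continue
            pts.append(parse_xy(line, i + 1))
            i += 1

        sid = specimen_id or f"specimen_{len(outlines) + 1}"
        if n_lm != 4:
            raise TPSFormatError(
                f"specimen '{sid}' (record at line {rec_start}): expected "
                f"LM=4 control points, got LM={n_lm}"
            )
        if n_curve_pts is not None and n_curve_pts != len(pts):
            raise TPSFormatError(
                f"specimen '{sid}': POINTS={n_curve_pts} but {len(pts)} "
                "coordinates found"
            )
        if not pts:
            raise TPSFormatError(f"specimen '{sid}': empty outline")
        try:
            outlines.append(
                Outline(np.array(pts), np.array(lm), sid, metadata)
            )
        except ValueError as exc:
            raise TPSFormatError(
                f"specimen '{sid}' (record at line {rec_start}): {exc}"
            ) from exc
    return outlines


def write_tps(outlines: list[Outline], path=None) -> str:
    """Serialize outlines to TPS text (full float precision, deterministic).

    Returns the text; also writes it to ``path`` when given.
    """
    chunks = []
    for o in outlines:
        lines = [f"LM={len(o.control_points)}"]
        lines += [f"{float(x)!r} {float(y)!r}" for x, y in o.control_points]
        lines.append("CURVES=1")
        lines.append(f"POINTS={o.n_points}")
        lines += [f"{float(x)!r} {float(y)!r}" for x, y in o.points]
        for k, v in o.metadata.items():
            lines.append(f"{k}={v}")
        lines.append(f"ID={o.specimen_id}")
        chunks.append("\n".join(lines))
    text = "\n".join(chunks)
    if chunks:
        text += "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def normalize_orientation(outline: Outline) -> Outline:
    """Return a copy traversed counter-clockwise, starting nearest the
    rostral midline control point.

    Idempotent; preserves the point multiset.  Raises on zero-area
    (degenerate) outlines.
    """
    pts = outline.points
    area = _signed_area(pts)
    if area == 0.0:
        raise ValueError(
            f"outline '{outline.specimen_id}': zero signed area, "
            "orientation undefined"
        )
    if area < 0:
        pts = pts[::-1]
    anchor = outline.control_points[CP_ROSTRAL]
    start = int(np.argmin(np.sum((pts - anchor) ** 2, axis=1)))
    pts = np.roll(pts, -start, axis=0)
    out = outline.copy()
    out.points = pts
    return out
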