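"""Optical probe geometry for a bilateral motor-cortex montage.

The probe model is a 2-D scalp-plane abstraction: optodes live on a
flattened patch per hemisphere, with x increasing to the subject's right
and y increasing toward the front of the head.  Long channels pair a
source and a detector at a nominal 3 cm separation; short channels pair a
source with a dedicated proximal detector at 0.8 cm and are sensitive to
superficial (scalp) hemodynamics only.

The default montage has 14 sources and 32 detectors forming 64 long
channels and 4 short channels, split symmetrically across hemispheres.
Per hemisphere the long-channel optodes sit on a triangular lattice of
3 cm pitch; the source subset was chosen so that exactly 32 lattice
source-detector pairs at 3 cm exist over 14 detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Channel", "ProbeLayout", "ProbeConfigError", "make_probe"]

_LATTICE_DY = 3.0 * np.sqrt(3.0) / 2.0  # row spacing of a 3 cm triangular lattice

# Per-hemisphere node indices (row, col) on a 5x5 triangular patch.
# Sources form no 3 cm source-detector pair that is left unwired: every
# source-detector pair at 3 cm is a channel, and there are exactly 32.
_DEFAULT_SOURCES = [(0, 2), (1, 0), (1, 3), (2, 2), (3, 0), (3, 3), (4, 2)]
_DEFAULT_DETECTORS = [
    (0, 1), (0, 3), (0, 4), (1, 1), (1, 2), (1, 4), (2, 0),
    (2, 1), (2, 3), (2, 4), (3, 1), (3, 2), (4, 1), (4, 3),
]
# Sources carrying a short-separation detector (anterior-medial positions).
_DEFAULT_SHORT_SOURCES = [1, 4]

# A reduced montage for small simulation studies: 2 sources and 10
# detectors per hemisphere, 12 long channels each, one short per side.
_COMPACT_SOURCES = [(1, 1), (3, 1)]
_COMPACT_DETECTORS = [
    (0, 1), (0, 2), (1, 0), (1, 2), (2, 1), (2, 2), (3, 0), (3, 2),
    (4, 1), (4, 2),
]
_COMPACT_SHORT_SOURCES = [0]


class ProbeConfigError(ValueError):
    """Raised when a requested probe geometry is infeasible."""


@dataclass(frozen=True)
class Channel:
    """One source-detector pair.

    Indices are 1-based over the full probe, following the usual
    Src/Det nomenclature of fNIRS montage diagrams.
    """

    source: int
    detector: int
    separation: float          # cm
    is_short: bool
    hemisphere: str            # "L" or "R"
    midpoint: tuple[float, float]  # cm, scalp plane


@dataclass
class ProbeLayout:
    """Scalp-plane probe geometry and channel table."""

    source_pos: np.ndarray      # (n_sources, 2) cm
    detector_pos: np.ndarray    # (n_detectors, 2) cm
    channels: list[Channel]
    wavelengths: tuple[float, float] = (760.0, 850.0)
    rois: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def long_idx(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels) if not c.is_short])

    @property
    def short_idx(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels) if c.is_short])

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([c.midpoint for c in self.channels])

    @property
    def separations(self) -> np.ndarray:
        return np.array([c.separation for c in self.channels])

    def roi_channels(self, roi: str) -> list[int]:
        if roi == "whole":
            return [i for i, c in enumerate(self.channels) if not c.is_short]
        if roi not in self.rois:
            raise KeyError(f"undefined ROI {roi!r}")
        return list(self.rois[roi])


def _lattice_xy(node: tuple[int, int]) -> tuple[float, float]:
    r, c = node
    return 3.0 * c + 1.5 * (r % 2), _LATTICE_DY * r


def _hemisphere_nodes(layout: str):
    if layout == "default":
        return _DEFAULT_SOURCES, _DEFAULT_DETECTORS, _DEFAULT_SHORT_SOURCES
    if layout == "compact":
        return _COMPACT_SOURCES, _COMPACT_DETECTORS, _COMPACT_SHORT_SOURCES
    raise ProbeConfigError(f"unknown layout preset {layout!r}")


def make_probe(
    layout: str = "default",
    long_separation: float = 3.0,
    short_separation: float = 0.8,
    hemisphere_gap: float = 4.0,
    navigated_target: tuple[float, float] | None = None,
    navigated_radius: float = 4.0,
) -> ProbeLayout:
    """Build a bilateral probe layout.

    Parameters
    ----------
    layout
        ``"default"`` (14 sources, 32 detectors, 64 long + 4 short
        channels), ``"compact"`` (4 sources, 22 detectors, 24 long + 2
        short), or ``"single"`` (one source-detector pair, no shorts).
    long_separation, short_separation
        Nominal separations in cm.  The lattice construction requires
        ``long_separation`` in [2.75, 3.25] so that channel separations
        stay within tolerance of the nominal 3 cm montage.
    hemisphere_gap
        Medial gap between the two hemisphere patches, cm.
    navigated_target
        Scalp-plane point defining the "navigated" ROI (long channels
        whose midpoint lies within ``navigated_radius``).  Defaults to
        the centre of the left-hemisphere patch, i.e. the left motor
        region the montage targets.
    """
    if long_separation <= 0 or short_separation <= 0:
        raise ProbeConfigError("separations must be positive")

    if layout == "single":
        src = np.array([[0.0, 0.0]])
        det = np.array([[long_separation, 0.0]])
        ch = [Channel(1, 1, long_separation, False, "L",
                      (long_separation / 2.0, 0.0))]
        probe = ProbeLayout(src, det, ch)
        probe.rois = {"left": [0], "right": [], "navigated": [0]}
        return probe

    if not (2.75 <= long_separation <= 3.25):
        raise ProbeConfigError(
            "lattice layouts require a long separation within 0.25 cm of 3 cm"
        )
    scale = long_separation / 3.0

    s_nodes, d_nodes, short_srcs = _hemisphere_nodes(layout)
    s_local = np.array([_lattice_xy(n) for n in s_nodes]) * scale
    d_local = np.array([_lattice_xy(n) for n in d_nodes]) * scale

    # Short detectors sit next to their source, offset toward the midline.
    off = short_separation / np.sqrt(2.0)
    short_local = np.array([s_local[i] + [-off, off] for i in short_srcs])

    def place(side: float, pts: np.ndarray) -> np.ndarray:
        out = pts.copy()
        out[:, 0] = side * (hemisphere_gap / 2.0 + pts[:, 0])
        return out

    source_pos, detector_pos, channels = [], [], []
    n_src_hemi, n_det_hemi = len(s_local), len(d_local) + len(short_local)
    for h, side in (("L", -1.0), ("R", 1.0)):
        src_off = len(source_pos)
        det_off = len(detector_pos)
        sp = place(side, s_local)
        dp = place(side, d_local)
        shp = place(side, short_local)
        source_pos.extend(sp)
        detector_pos.extend(dp)
        detector_pos.extend(shp)
        for si, s in enumerate(sp):
            for di, d in enumerate(dp):
                sep = float(np.hypot(*(s - d)))
                if abs(sep - long_separation) < 0.25:
                    channels.append(Channel(
                        src_off + si + 1, det_off + di + 1, sep, False, h,
                        tuple((s + d) / 2.0)))
        for k, si in enumerate(short_srcs):
            s = sp[si]
            d = shp[k]
            sep = float(np.hypot(*(s - d)))
            channels.append(Channel(
                src_off + si + 1, det_off + len(dp) + k + 1, sep, True, h,
                tuple((s + d) / 2.0)))

    probe = ProbeLayout(np.array(source_pos), np.array(detector_pos), channels)

    n_long_hemi = sum(1 for c in channels if not c.is_short and c.hemisphere == "L")
    expected = {"default": 32, "compact": 12}[layout]
    if n_long_hemi != expected:
        raise ProbeConfigError(
            f"lattice produced {n_long_hemi} long channels per hemisphere, "
            f"expected {expected}; separation/gap combination infeasible")

    if navigated_target is None:
        left_long = [c.midpoint for c in channels
                     if not c.is_short and c.hemisphere == "L"]
        navigated_target = tuple(np.mean(left_long, axis=0))
    mids = probe.midpoints
    nav = [i for i, c in enumerate(channels)
           if not c.is_short
           and np.hypot(mids[i, 0] - navigated_target[0],
                        mids[i, 1] - navigated_target[1]) <= navigated_radius]
    probe.rois = {
        "left": [i for i, c in enumerate(channels)
                 if not c.is_short and c.hemisphere == "L"],
        "right": [i for i, c in enumerate(channels)
                  if not c.is_short and c.hemisphere == "R"],
        "navigated": nav,
    }
    return probe
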