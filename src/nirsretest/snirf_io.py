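"""SNIRF (HDF5) reading and writing for raw intensity recordings.

Implements the subset of SNIRF v1.0 needed for continuous-wave
amplitude data: ``/nirs/data1`` with one measurementList entry per
(channel, wavelength), 2-D probe optode positions, stimulus blocks, and
metadata tags.  Ground truth and physiology travel in TSV sidecars
written next to the SNIRF file by the simulator CLI.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .probe import Channel, ProbeLayout
from .synth import PhysioReading, RawRecording, StimSchedule

__all__ = ["write_snirf", "read_snirf", "SnirfFormatError"]


class SnirfFormatError(ValueError):
    """Missing or malformed required SNIRF field."""


def _str(v) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)


def write_snirf(rec: RawRecording, path: str | Path) -> Path:
    """Write a raw recording as a SNIRF file."""
    path = Path(path)
    n_ch = rec.n_channels
    n_t = rec.n_times
    # (time, measurement): channel-major, wavelength-minor
    data = rec.intensity.reshape(n_ch * 2, n_t).T
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID",
                            data=str(rec.meta.get("subject", "unknown")))
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        for key in ("session", "condition", "time_of_day", "day"):
            if key in rec.meta:
                meta.create_dataset(key, data=str(rec.meta[key]))
        if rec.physio is not None:
            ph = rec.physio
            meta.create_dataset("physio", data=";".join(
                f"{k}={getattr(ph, k):.6g}"
                for k in ("hr_pre", "hr_post", "map_pre", "map_post")))

        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=rec.times)
        for m, ch in enumerate(rec.probe.channels):
            for w in (0, 1):
                ml = d1.create_group(f"measurementList{2 * m + w + 1}")
                ml.create_dataset("sourceIndex", data=np.int32(ch.source))
                ml.create_dataset("detectorIndex", data=np.int32(ch.detector))
                ml.create_dataset("wavelengthIndex", data=np.int32(w + 1))
                ml.create_dataset("dataType", data=np.int32(1))  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=np.int32(1))

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths",
                             data=np.asarray(rec.probe.wavelengths, float))
        probe.create_dataset("sourcePos2D", data=rec.probe.source_pos)
        probe.create_dataset("detectorPos2D", data=rec.probe.detector_pos)

        stim = nirs.create_group("stim1")
        stim.create_dataset("name", data="task")
        onsets = rec.schedule.onsets
        stim.create_dataset("data", data=np.column_stack([
            onsets, np.full_like(onsets, rec.schedule.duration),
            np.ones_like(onsets)]))
    return path


def _require(group, name):
    if name not in group:
        raise SnirfFormatError(f"missing required SNIRF field {group.name}/{name}")
    return group[name]


def read_snirf(path: str | Path) -> RawRecording:
    """Read a SNIRF file written by :func:`write_snirf` (or compatible).

    Files without a stimulus group load with an empty schedule and a
    warning in ``meta['warnings']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    warnings: list[str] = []
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else (
            f["nirs1"] if "nirs1" in f else None)
        if nirs is None:
            raise SnirfFormatError("missing required SNIRF group /nirs")
        d1 = _require(nirs, "data1")
        data = np.asarray(_require(d1, "dataTimeSeries"))
        time = np.asarray(_require(d1, "time"))
        if len(time) < 2:
            raise SnirfFormatError("time axis too short")
        fs = float(1.0 / np.median(np.diff(time)))

        probe_g = _require(nirs, "probe")
        wavelengths = tuple(np.asarray(_require(probe_g, "wavelengths"), float))
        src_pos = np.asarray(_require(probe_g, "sourcePos2D"), float)
        det_pos = np.asarray(_require(probe_g, "detectorPos2D"), float)

        # measurement list -> unique (source, detector) channels in order
        n_meas = data.shape[1]
        meas = []
        for m in range(1, n_meas + 1):
            ml = _require(d1, f"measurementList{m}")
            meas.append((int(ml["sourceIndex"][()]),
                         int(ml["detectorIndex"][()]),
                         int(ml["wavelengthIndex"][()])))
        chan_keys: list[tuple[int, int]] = []
        for s, d, _w in meas:
            if (s, d) not in chan_keys:
                chan_keys.append((s, d))
        n_ch = len(chan_keys)
        if n_ch * 2 != n_meas:
            raise SnirfFormatError(
                "expected exactly two wavelengths per channel")
        intensity = np.empty((n_ch, 2, data.shape[0]))
        for m, (s, d, w) in enumerate(meas):
            intensity[chan_keys.index((s, d)), w - 1] = data[:, m]

        channels = []
        for s, d in chan_keys:
            sp, dp = src_pos[s - 1], det_pos[d - 1]
            sep = float(np.hypot(*(sp - dp)))
            mid = tuple((sp + dp) / 2.0)
            channels.append(Channel(
                source=s, detector=d, separation=sep,
                is_short=sep < 1.5, hemisphere="L" if mid[0] < 0 else "R",
                midpoint=mid))
        probe = ProbeLayout(source_pos=src_pos, detector_pos=det_pos,
                            channels=channels, wavelengths=wavelengths)
        long_l = [i for i, c in enumerate(channels)
                  if not c.is_short and c.hemisphere == "L"]
        long_r = [i for i, c in enumerate(channels)
                  if not c.is_short and c.hemisphere == "R"]
        probe.rois = {"left": long_l, "right": long_r}
        if long_l:
            mids = probe.midpoints
            centre = mids[long_l].mean(axis=0)
            probe.rois["navigated"] = [
                i for i in long_l
                if np.hypot(*(mids[i] - centre)) <= 4.0]

        if "stim1" in nirs:
            sd = np.atleast_2d(np.asarray(nirs["stim1"]["data"]))
            onsets = sd[:, 0]
            dur = float(sd[0, 1]) if sd.size else 0.0
        else:
            warnings.append("no stimulus group; schedule is empty")
            onsets = np.array([])
            dur = 0.0
        schedule = StimSchedule(onsets=onsets, duration=dur,
                                total_duration=float(time[-1]) + 1.0 / fs)

        meta: dict = {}
        physio = None
        if "metaDataTags" in nirs:
            tags = nirs["metaDataTags"]
            for key, out in (("SubjectID", "subject"), ("session", "session"),
                             ("condition", "condition"),
                             ("time_of_day", "time_of_day"), ("day", "day")):
                if key in tags:
                    meta[out] = _str(tags[key][()])
            if "physio" in tags:
                vals = dict(kv.split("=")
                            for kv in _str(tags["physio"][()]).split(";"))
                physio = PhysioReading(**{k: float(v) for k, v in vals.items()})
        if warnings:
            meta["warnings"] = warnings
    return RawRecording(intensity=intensity, fs=fs, probe=probe,
                        schedule=schedule, meta=meta, physio=physio)
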