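"""Readers and writers: HDF5 RF exam containers, cohort manifests, tables.

One exam = one HDF5 file with datasets ``slices/<i>/rf`` (float32,
axial x lateral) and ``slices/<i>/mask`` (uint8) plus scalar attributes
``fs``, ``fc``, ``c``, ``pitch``, ``focal_depth``, ``patient_id``.  Raw RF
has no standard consumer format, so a self-describing hierarchical container
is used instead of DICOM.  Cohort manifest is a CSV
``patient_id,label,survival_months,event``.
"""

from __future__ import annotations


import h5py
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, LABELS
from .simulate import AcquisitionSpec, RFExam, TissueSpec

__all__ = [
    "write_exam",
    "read_exam",
    "write_parametric_maps",
    "write_window_debug",
    "write_texture_debug",
    "write_manifest",
    "read_manifest",
    "write_feature_table",
    "read_feature_table",
]

_TRUTH_FIELDS = ("effective_scatterer_radius", "acoustic_concentration",
                 "mean_regular_spacing", "spacing_jitter",
                 "attenuation_coeff", "scatterer_density")


def write_exam(path, exam: RFExam) -> None:
    acq = exam.acquisition
    with h5py.File(path, "w") as h:
        h.attrs["fs"] = acq.sampling_frequency
        h.attrs["fc"] = acq.center_frequency
        h.attrs["band_low"] = acq.band_low
        h.attrs["band_high"] = acq.band_high
        h.attrs["c"] = acq.sound_speed
        h.attrs["pitch"] = acq.lateral_pitch
        h.attrs["focal_depth"] = acq.focal_depth
        h.attrs["patient_id"] = exam.patient_id
        for i, (rf, mask) in enumerate(zip(exam.slices, exam.masks)):
            g = h.create_group(f"slices/{i}")
            g.create_dataset("rf", data=rf.astype(np.float32))
            g.create_dataset("mask", data=mask.astype(np.uint8))
        if exam.truth is not None:
            t = h.create_group("truth")
            for f in _TRUTH_FIELDS:
                t.attrs[f] = getattr(exam.truth, f)


def read_exam(path) -> RFExam:
    with h5py.File(path, "r") as h:
        for attr in ("fs", "fc", "c", "pitch", "patient_id"):
            if attr not in h.attrs:
                raise ValueError(f"exam container missing attribute {attr!r}")
        if "slices" not in h:
            raise ValueError("exam container missing dataset path 'slices'")
        keys = sorted(h["slices"].keys(), key=int)
        slices, masks = [], []
        for k in keys:
            g = h[f"slices/{k}"]
            if "rf" not in g or "mask" not in g:
                raise ValueError(f"slices/{k} missing 'rf' or 'mask' dataset")
            slices.append(g["rf"][()].astype(np.float64))
            masks.append(g["mask"][()].astype(np.uint8))
        rf0 = slices[0]
        acq = AcquisitionSpec(
            sampling_frequency=float(h.attrs["fs"]),
            center_frequency=float(h.attrs["fc"]),
            band_low=float(h.attrs.get("band_low", 3e6)),
            band_high=float(h.attrs.get("band_high", 8e6)),
            sound_speed=float(h.attrs["c"]),
            lateral_pitch=float(h.attrs["pitch"]),
            n_axial_samples=rf0.shape[0],
            n_lines=rf0.shape[1],
            focal_depth=float(h.attrs.get("focal_depth", 2e-2)),
        )
        truth = None
        if "truth" in h:
            truth = TissueSpec(**{f: float(h["truth"].attrs[f])
                                  for f in _TRUTH_FIELDS})
        pid = h.attrs["patient_id"]
        pid = pid.decode() if isinstance(pid, bytes) else str(pid)
        return RFExam(patient_id=pid, slices=slices, masks=masks,
                      acquisition=acq, truth=truth)


def write_parametric_maps(path, extraction) -> None:
    """Per-exam intermediate output: ``slices/<i>/maps/<param>`` (float32
    lattices, NaN outside the ROI) plus the per-slice ``ace`` scalar."""
    with h5py.File(path, "w") as h:
        h.attrs["patient_id"] = extraction.features.name or "exam"
        for i, sf in enumerate(extraction.slices):
            g = h.create_group(f"slices/{i}")
            g.attrs["ace"] = sf.ace
            g.attrs["n_windows"] = sf.n_windows
            for param, grid in sf.maps.items():
                g.create_dataset(f"maps/{param}",
                                 data=grid.astype(np.float32))


def write_window_debug(path, extraction) -> None:
    """Per-window estimate CSV: one row per (slice, window)."""
    frames = []
    for i, sf in enumerate(extraction.slices):
        df = pd.DataFrame(sf.window_values)
        df.insert(0, "col", sf.grid.positions[:, 1])
        df.insert(0, "row", sf.grid.positions[:, 0])
        df.insert(0, "slice", i)
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False, float_format="%.10g")


def write_texture_debug(path, patient_id, extraction,
                        n_levels=None) -> None:
    """Per-offset GLCM feature CSV:
    patient_id,slice,param,distance,angle,ENE,CON,HOM,COR."""
    from . import texture as tex
    n_levels = n_levels or tex.N_LEVELS
    rows = []
    for i, sf in enumerate(extraction.slices):
        for param in tex.QUANTIZATION_RANGES:
            q = tex.quantize_map(sf.maps[param],
                                 tex.QUANTIZATION_RANGES[param], n_levels)
            for rec in tex.offset_features(q, n_levels=n_levels):
                rows.append({"patient_id": patient_id, "slice": i,
                             "param": param, **rec})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_manifest(path, patient_ids, labels, survival_months, event) -> None:
    df = pd.DataFrame({
        "patient_id": patient_ids,
        "label": labels,
        "survival_months": np.asarray(survival_months, dtype=float),
        "event": np.asarray(event, dtype=bool).astype(int),
    })
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["patient_id", "label", "survival_months", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing column(s): {missing}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"manifest label(s) outside {LABELS}: {sorted(bad)}")
    df["event"] = df["event"].astype(bool)
    return df


def write_feature_table(path, table: pd.DataFrame) -> None:
    cols = list(FEATURE_NAMES) + [c for c in ("label", "survival_months",
                                              "event") if c in table.columns]
    table[cols].to_csv(path, index=True, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="patient_id")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    if "label" in df.columns:
        bad = set(df["label"]) - set(LABELS)
        if bad:
            raise ValueError(
                f"feature table label(s) outside {LABELS}: {sorted(bad)}")
    if "event" in df.columns:
        df["event"] = df["event"].astype(bool)
    return df
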