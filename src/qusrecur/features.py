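"""Patient-level feature assembly, normalization and univariate statistics.

A patient's feature vector has 31 entries: the seven primary QUS parameters
(MBF, SS, SI, AAC, ASD, ACE, SAS; window estimates averaged per slice, then
area-weighted across slices) plus 24 GLCM texture features (4 statistics for
each of the six parametric maps, area-weighted across slices).  ACE is a
per-slice scalar and has no parametric map, hence no texture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import spectra, texture
from .simulate import RFExam

__all__ = [
    "PRIMARY_PARAMS",
    "TEXTURE_PARAMS",
    "TEXTURE_STATS",
    "FEATURE_NAMES",
    "LABELS",
    "extract_patient_features",
    "build_cohort_table",
    "zscore_normalize",
    "apply_zscore",
    "univariate_tests",
]

log = logging.getLogger(__name__)

PRIMARY_PARAMS = ("MBF", "SS", "SI", "AAC", "ASD", "ACE", "SAS")
TEXTURE_PARAMS = ("MBF", "SS", "SI", "AAC", "ASD", "SAS")
TEXTURE_STATS = ("ENE", "CON", "HOM", "COR")
FEATURE_NAMES: tuple[str, ...] = PRIMARY_PARAMS + tuple(
    f"{p}-{s}" for p in TEXTURE_PARAMS for s in TEXTURE_STATS)
LABELS = ("recurrence", "no_recurrence")

META_COLUMNS = ("label", "survival_months", "event")


@dataclass
class PatientExtraction:
    """Feature vector plus per-slice diagnostics for one patient."""

    features: pd.Series
    slices: list[spectra.SliceFeatures]

    @property
    def aggregates(self) -> dict[str, float]:
        """Area-weighted ROI-aggregate estimates (recovery diagnostics)."""
        areas = [s.area for s in self.slices]
        return {k: texture.aggregate_slices(
                    [s.aggregates[k] for s in self.slices], areas)
                for k in self.slices[0].aggregates}


def extract_patient_features(exam: RFExam, phantom: RFExam, *,
                             window_mm: float = spectra.WINDOW_MM,
                             n_levels: int = texture.N_LEVELS
                             ) -> PatientExtraction:
    """Run spectral + texture extraction for one exam against a phantom.

    ``phantom`` may be an RFExam (all frames averaged into the reference) or
    a pre-built spectra.PhantomReference shared across patients.
    """
    if isinstance(phantom, spectra.PhantomReference):
        ref = phantom
    else:
        ref = spectra.PhantomReference(phantom.slices)
    per_slice = [
        spectra.extract_slice(rf, mask, ref, exam.acquisition,
                              window_mm=window_mm)
        for rf, mask in zip(exam.slices, exam.masks)
    ]
    areas = [s.area for s in per_slice]
    values: dict[str, float] = {}
    for p in PRIMARY_PARAMS:
        per = [s.ace if p == "ACE" else s.window_means[p] for s in per_slice]
        values[p] = texture.aggregate_slices(per, areas)
    for p in TEXTURE_PARAMS:
        per_tex = []
        for s in per_slice:
            q = texture.quantize_map(s.maps[p],
                                     texture.QUANTIZATION_RANGES[p],
                                     n_levels)
            per_tex.append(texture.glcm_features(q, n_levels=n_levels))
        for stat in TEXTURE_STATS:
            values[f"{p}-{stat}"] = texture.aggregate_slices(
                [t[stat] for t in per_tex], areas)
    flagged = {k: sum(s.flags.get(k, 0) for s in per_slice)
               for k in per_slice[0].flags}
    if any(flagged.values()):
        log.info("patient %s flagged estimates: %s", exam.patient_id, flagged)
    series = pd.Series([values[n] for n in FEATURE_NAMES],
                       index=list(FEATURE_NAMES), name=exam.patient_id)
    return PatientExtraction(features=series, slices=per_slice)


def build_cohort_table(exams: list[RFExam], labels: list[str],
                       survival_months, event, phantom: RFExam, *,
                       window_mm: float = spectra.WINDOW_MM) -> pd.DataFrame:
    """Patients x (31 features + label + survival + event flag).

    Exams whose extraction fails are excluded with a log entry; an empty
    input (or all-failed extraction) raises.
    """
    if len(exams) == 0:
        raise ValueError("no exams provided")
    if not (len(exams) == len(labels) == len(survival_months) == len(event)):
        raise ValueError("exams, labels and survival records must align")
    ref = spectra.PhantomReference(phantom.slices)
    rows, idx, meta = [], [], []
    for i, exam in enumerate(exams):
        if labels[i] not in LABELS:
            raise ValueError(f"unknown label {labels[i]!r}")
        try:
            ext = extract_patient_features(exam, ref,
                                           window_mm=window_mm)
        except Exception:
            log.exception("extraction failed for %s; excluded",
                          exam.patient_id)
            continue
        rows.append(ext.features)
        idx.append(exam.patient_id)
        meta.append((labels[i], float(survival_months[i]), bool(event[i])))
    if not rows:
        raise ValueError("extraction failed for every exam")
    table = pd.DataFrame(rows, index=idx)
    table.index.name = "patient_id"
    table["label"] = [m[0] for m in meta]
    table["survival_months"] = [m[1] for m in meta]
    table["event"] = [m[2] for m in meta]
    return table


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    return table[list(FEATURE_NAMES)]


def zscore_normalize(table: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each feature column with sample (n-1) statistics.

    Returns the normalized table and a (mean, sd) stats frame for reuse on
    held-out rows.  Zero-variance columns raise, naming the column.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 patients to normalize")
    x = feature_matrix(table)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    bad = sd[sd <= 0]
    if len(bad):
        raise ValueError(f"zero-variance feature column: {bad.index[0]}")
    out = table.copy()
    out[list(FEATURE_NAMES)] = (x - mean) / sd
    stats_df = pd.DataFrame({"mean": mean, "sd": sd})
    return out, stats_df


def apply_zscore(rows: pd.DataFrame, stats_df: pd.DataFrame) -> pd.DataFrame:
    """Transform held-out rows with previously computed training statistics."""
    out = rows.copy()
    out[list(FEATURE_NAMES)] = (
        (rows[list(FEATURE_NAMES)] - stats_df["mean"]) / stats_df["sd"])
    return out


def synthetic_feature_table(n_recurrence: int = 8, n_no_recurrence: int = 16,
                            separation_sd: float = 5.0, n_separated: int = 4,
                            seed: int = 0, permute_labels: bool = False,
                            hazard_recurrence: float = np.log(2) / 9.0,
                            hazard_no_recurrence: float = np.log(2) / 42.0,
                            censoring_time: float = 64.0) -> pd.DataFrame:
    """Feature-level synthetic cohort for exercising the classifier engine.

    Within-class scatter is uniform (bounded), so a class gap of
    ``separation_sd`` within-class standard deviations on the first
    ``n_separated`` informative features (ASD, SAS, ASD-CON, SAS-CON) leaves
    a true margin between the classes once separation_sd exceeds ~3.5; the
    remaining columns are pure noise.  Survival is exponential per class,
    censored for the no-recurrence group.  ``permute_labels`` shuffles the
    labels (and outcomes) for null-calibration checks.
    """
    rng = np.random.default_rng(seed)
    n = n_recurrence + n_no_recurrence
    y = np.array([1] * n_recurrence + [0] * n_no_recurrence)
    x = rng.uniform(-1.0, 1.0, (n, len(FEATURE_NAMES)))
    sd_u = 1.0 / np.sqrt(3.0)   # sd of uniform(-1, 1)
    informative = ["ASD", "SAS", "ASD-CON", "SAS-CON"][:n_separated]
    for name in informative:
        x[:, FEATURE_NAMES.index(name)] += separation_sd * sd_u * y
    if permute_labels:
        y = rng.permutation(y)
    df = pd.DataFrame(x, columns=list(FEATURE_NAMES),
                      index=[f"S{i:03d}" for i in range(n)])
    df.index.name = "patient_id"
    df["label"] = np.where(y == 1, "recurrence", "no_recurrence")
    t = np.where(
        y == 1,
        -np.log1p(-rng.uniform(size=n)
                  * (1 - np.exp(-hazard_recurrence * censoring_time)))
        / hazard_recurrence,
        np.minimum(rng.exponential(1.0 / hazard_no_recurrence, size=n),
                   censoring_time))
    df["survival_months"] = t
    df["event"] = y == 1
    return df


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0.0:
        return 0.0   # degenerate (constant) sample: treat as non-normal
    return float(stats.shapiro(x).pvalue)


def univariate_tests(table: pd.DataFrame, alpha: float = 0.05
                     ) -> pd.DataFrame:
    """Two-group comparison per feature.

    Shapiro-Wilk per group; if both groups look normal (p >= alpha) a Welch
    two-sided t-test is used, otherwise a two-sided Mann-Whitney U (exact
    when the combined sample is <= 20 and tie-free, normal approximation
    with tie correction otherwise).
    """
    g1 = table[table["label"] == "recurrence"]
    g0 = table[table["label"] == "no_recurrence"]
    if len(g1) < 3 or len(g0) < 3:
        raise ValueError("each group needs >= 3 patients")
    records = []
    for name in FEATURE_NAMES:
        a = g1[name].to_numpy(dtype=float)
        b = g0[name].to_numpy(dtype=float)
        pa, pb = _shapiro_p(a), _shapiro_p(b)
        if pa >= alpha and pb >= alpha:
            test = "t"
            if np.ptp(np.concatenate([a, b])) == 0.0:
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                if not np.isfinite(p):
                    p = 1.0
        else:
            test = "mannwhitney"
            method = "exact" if len(a) + len(b) <= 20 else "asymptotic"
            try:
                p = float(stats.mannwhitneyu(
                    a, b, alternative="two-sided", method=method).pvalue)
            except ValueError:
                p = 1.0
        records.append({
            "feature": name,
            "shapiro_p_recurrence": pa,
            "shapiro_p_no_recurrence": pb,
            "test": test,
            "p_value": p,
            "mean_recurrence": float(a.mean()),
            "mean_no_recurrence": float(b.mean()),
            "significant": p < alpha,
        })
    return pd.DataFrame.from_records(records).set_index("feature")
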