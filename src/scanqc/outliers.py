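"""Cohort-level outlier detection: IQR plus four multivariate detectors,
aggregated into a 0-5 majority vote per scan.

Each sequence class contributes its own feature table (anatomical:
snr_standard_db + snr_chang_db; diffusion: those plus motion_severity;
functional: tsnr_db + motion_severity).  One univariate rule (quartiles
± 1.5 IQR, applied one-sidedly in the bad-quality direction) and four
multivariate detectors (one-class SVM, isolation forest, local outlier
factor, elliptic envelope) each cast a binary vote; the sum 0-5 is the
scan's outlier score, thresholded for review at the user's strictness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import EllipticEnvelope
from sklearn.ensemble import IsolationForest
from sklearn.neighbors import LocalOutlierFactor
from sklearn.svm import OneClassSVM

log = logging.getLogger(__name__)

DETECTORS = ("iqr", "ocsvm", "iforest", "lof", "ee")
MULTIVARIATE = DETECTORS[1:]

#: expected feature columns per sequence class
CLASS_FEATURES = {
    "anatomical": ("snr_standard_db", "snr_chang_db"),
    "diffusion": ("snr_standard_db", "snr_chang_db", "motion_severity"),
    "functional": ("tsnr_db", "motion_severity"),
}

#: quality polarity: +1 means higher is better (low tail is bad),
#: -1 means lower is better (high tail is bad)
FEATURE_POLARITY = {
    "snr_standard_db": +1,
    "snr_chang_db": +1,
    "tsnr_db": +1,
    "motion_severity": -1,
}


@dataclass
class VoteRecord:
    """Five binary outlier flags and their sum for one scan."""

    flags: dict[str, bool]

    def __post_init__(self) -> None:
        if set(self.flags) != set(DETECTORS):
            raise ValueError(f"flags must name exactly {DETECTORS}")

    @property
    def majority_vote(self) -> int:
        return majority_vote(self.flags)


def majority_vote(flags: dict[str, bool]) -> int:
    """Number of detectors voting 'outlier' (0 = clean in all, 5 = all)."""
    if set(flags) != set(DETECTORS):
        raise ValueError(f"flags must name exactly {DETECTORS}")
    return int(sum(bool(v) for v in flags.values()))


def _finite_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Numeric feature matrix, row-usability mask, and feature names.

    Non-finite entries (failed features, zero-noise sentinels) make a row
    unusable for multivariate detection; they are excluded from fitting and
    voted 'not an outlier' by the affected detectors, with a log entry.
    """
    cols = [c for c in table.columns if c in FEATURE_POLARITY]
    X = table[cols].to_numpy(dtype=np.float64)
    usable = np.isfinite(X).all(axis=1) if cols else np.zeros(len(table), bool)
    return X, usable, cols


def iqr_flags(table: pd.DataFrame) -> pd.Series:
    """One-sided quartile rule per feature.

    A scan is flagged iff any feature violates its quality polarity:
    SNR-like features below Q1 - 1.5 IQR, motion severity above
    Q3 + 1.5 IQR (linear-interpolation quantiles).  Features with fewer
    than 4 finite values are skipped.
    """
    flags = pd.Series(False, index=table.index)
    for col in table.columns:
        polarity = FEATURE_POLARITY.get(col)
        if polarity is None:
            continue
        values = pd.to_numeric(table[col], errors="coerce").to_numpy(np.float64)
        finite = np.isfinite(values)
        if finite.sum() < 4:
            log.info("iqr: feature %s has <4 values, skipped", col)
            continue
        q1, q3 = np.quantile(values[finite], [0.25, 0.75])
        iqr = q3 - q1
        if polarity > 0:
            violation = values < q1 - 1.5 * iqr
        else:
            violation = values > q3 + 1.5 * iqr
        flags |= pd.Series(violation & finite, index=table.index)
    return flags


def _make_detector(method: str, n: int, seed: int, config: dict):
    if method == "ocsvm":
        return OneClassSVM(kernel="rbf", nu=config.get("ocsvm_nu", 0.05))
    if method == "iforest":
        return IsolationForest(
            contamination=config.get("iforest_contamination", 0.05),
            n_estimators=config.get("iforest_n_estimators", 100),
            random_state=seed,
        )
    if method == "lof":
        return LocalOutlierFactor(
            n_neighbors=min(config.get("lof_n_neighbors", 20), n - 1),
            contamination=config.get("lof_contamination", 0.05),
        )
    if method == "ee":
        return EllipticEnvelope(
            contamination=config.get("ee_contamination", 0.05),
            random_state=seed,
        )
    raise ValueError(f"unknown method {method!r}")


def multivariate_flags(
    table: pd.DataFrame,
    method: str,
    seed: int = 0,
    **config,
) -> pd.Series:
    """Outlier decisions of one multivariate detector over a cohort table.

    Features are z-scored per cohort (dB and MI-std scales differ by orders
    of magnitude).  The standardized matrix is fitted in a canonical row
    order (lexicographic by feature values) so permuting the input rows
    permutes the flags identically; decisions are mapped back to the input
    order.  Degenerate cohorts (no variance) and fit failures yield
    all-false flags with a log entry, never an exception.
    """
    if method not in MULTIVARIATE:
        raise ValueError(f"method must be one of {MULTIVARIATE}")
    flags = pd.Series(False, index=table.index)
    X, usable, cols = _finite_matrix(table)
    n = int(usable.sum())
    dropped = len(table) - n
    if dropped:
        log.info("%s: %d row(s) with missing features excluded", method, dropped)
    if n < 2:
        log.warning("%s: %d usable row(s), skipping detection", method, n)
        return flags
    if n < 10:
        log.warning("%s: only %d rows — decisions may be unstable", method, n)

    Xu = X[usable]
    mu = Xu.mean(axis=0)
    sd = Xu.std(axis=0)
    if not np.any(sd > 0):
        log.info("%s: cohort has zero feature variance, no outliers separable",
                 method)
        return flags
    sd[sd == 0] = 1.0
    Z = (Xu - mu) / sd

    order = np.lexsort(Z.T[::-1])  # canonical fit order
    inverse = np.argsort(order)
    try:
        detector = _make_detector(method, n, seed, config)
        if method == "lof":
            labels = np.asarray(detector.fit_predict(Z[order]))[inverse]
        else:
            detector.fit(Z[order])
            labels = np.asarray(detector.predict(Z))
    except Exception as exc:  # e.g. singular covariance in EE
        log.warning("%s failed (%s); contributing no flags", method, exc)
        return flags
    flags.iloc[np.flatnonzero(usable)] = labels == -1
    return flags


def vote_table(
    table: pd.DataFrame,
    seed: int = 0,
    threshold: int = 3,
    **config,
) -> pd.DataFrame:
    """All five detector flags, the majority vote, and the review flag.

    Returns a frame indexed like ``table`` with integer 0/1 columns per
    detector, ``majority_vote`` (their row sum) and ``flagged``
    (vote >= threshold).
    """
    if not 1 <= threshold <= 5:
        raise ValueError("review threshold must be in 1..5")
    out = pd.DataFrame(index=table.index)
    out["iqr"] = iqr_flags(table).astype(int)
    for method in MULTIVARIATE:
        out[method] = multivariate_flags(table, method, seed=seed, **config).astype(int)
    out["majority_vote"] = out[list(DETECTORS)].sum(axis=1)
    out["flagged"] = out["majority_vote"] >= threshold
    return out


def run_outlier_stage(
    tables: dict[str, pd.DataFrame | list[pd.DataFrame]],
    mode: str = "per_dataset",
    threshold: int = 3,
    seed: int = 0,
    **config,
) -> dict[str, pd.DataFrame]:
    """Stage III over per-class feature tables.

    ``tables`` maps sequence class to one feature table, or to a list of
    tables (one per dataset).  In ``collective`` mode the datasets of a
    class are pooled into one cohort before detection; in ``per_dataset``
    mode each is processed independently and the results concatenated.
    Empty classes are skipped with a log entry.
    """
    if mode not in ("per_dataset", "collective"):
        raise ValueError(f"unknown mode {mode!r}")
    results: dict[str, pd.DataFrame] = {}
    for cls, entry in tables.items():
        parts = entry if isinstance(entry, list) else [entry]
        parts = [p for p in parts if p is not None and len(p)]
        if not parts:
            log.info("outlier stage: class %s empty, skipped", cls)
            continue
        if mode == "collective" and len(parts) > 1:
            pooled = pd.concat(parts, axis=0)
            results[cls] = vote_table(pooled, seed=seed, threshold=threshold, **config)
        else:
            votes = [
                vote_table(p, seed=seed, threshold=threshold, **config) for p in parts
            ]
            results[cls] = pd.concat(votes, axis=0)
    return results
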