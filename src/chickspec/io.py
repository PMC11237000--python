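"""File formats, run configuration and the end-to-end pipeline.

Spectra travel as two-column plain text (wavenumber_cm1, intensity; ``#``
comments; header optional), cohorts as a manifest CSV pointing at the
per-spectrum files.  :func:`run_pipeline` chains simulate → preprocess →
stats → decompose → sex into one reproducible, fully logged run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import band_stats, chemometrics, preprocessing, sexing, synthetic
from .spectra import Spectrum, SpectrumSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "write_cohort",
    "read_cohort",
    "RunConfig",
    "run_pipeline",
]


class SpectrumParseError(ValueError):
    pass


def read_spectrum(path: str | Path, meta: dict | None = None) -> Spectrum:
    """Parse a two-column text spectrum; the axis is sorted ascending on read."""
    path = Path(path)
    wn, it = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 or (not wn and lineno <= 2):
                    continue  # tolerated header line
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
            wn.append(w)
            it.append(v)
    if len(wn) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data points")
    wn_arr = np.array(wn)
    it_arr = np.array(it)
    order = np.argsort(wn_arr, kind="stable")
    wn_arr, it_arr = wn_arr[order], it_arr[order]
    dup = np.flatnonzero(np.diff(wn_arr) == 0)
    if dup.size:
        raise SpectrumParseError(
            f"{path}: duplicate wavenumber {wn_arr[dup[0]]:g} cm⁻¹"
        )
    return Spectrum(wn_arr, it_arr, dict(meta or {}))


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("wavenumber_cm1,intensity\n")
        for w, v in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{float(w)!r},{float(v)!r}\n")


_MANIFEST_COLS = ["sample_id", "sex", "component", "state", "path", "true_oxy_fraction"]


def write_cohort(spectra: SpectrumSet, out_dir: str | Path) -> Path:
    """Write per-spectrum CSVs plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(spectra):
        sid = s.meta.get("sample_id", f"S{i:03d}")
        rel = f"{sid}.csv"
        write_spectrum(s, out_dir / rel)
        rows.append(
            {
                "sample_id": sid,
                "sex": s.meta.get("sex", "unknown"),
                "component": s.meta.get("component", "whole_blood"),
                "state": s.meta.get("state", "ambient"),
                "path": rel,
                "true_oxy_fraction": s.meta.get("true_oxy_fraction", ""),
            }
        )
    manifest = pd.DataFrame(rows, columns=_MANIFEST_COLS)
    if manifest["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in cohort")
    mpath = out_dir / "manifest.csv"
    manifest.to_csv(mpath, index=False)
    return mpath


def read_cohort(manifest_path: str | Path) -> SpectrumSet:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    if manifest["sample_id"].duplicated().any():
        raise ValueError(f"{manifest_path}: duplicate sample_ids")
    base = manifest_path.parent
    spectra = []
    for row in manifest.itertuples(index=False):
        p = base / row.path
        if not p.exists():
            raise FileNotFoundError(f"{manifest_path}: referenced spectrum {p} missing")
        meta = {
            "sample_id": row.sample_id,
            "sex": row.sex,
            "component": row.component,
            "state": row.state,
        }
        f = getattr(row, "true_oxy_fraction", "")
        if f != "" and not pd.isna(f):
            meta["true_oxy_fraction"] = float(f)
        spectra.append(read_spectrum(p, meta))
    return SpectrumSet(spectra)


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    if "grid" in data and isinstance(data["grid"], list):
        data = {**data, "grid": tuple(data["grid"])}
    if "normalization_region" in data and isinstance(data["normalization_region"], list):
        data = {**data, "normalization_region": tuple(data["normalization_region"])}
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Nested configuration of one end-to-end run; round-trips through YAML."""

    synthetic: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    preprocessing: preprocessing.PreprocessConfig = field(
        default_factory=preprocessing.PreprocessConfig
    )
    n_bands: int = 4
    min_separation_cm1: float = 10.0
    n_pls_factors: int = 6
    n_pcs_considered: int = 8
    seed: int = 0
    out_dir: str = "chickspec_run"

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fanned out from the global seed."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode()) % 2**31])
        return int(ss.generate_state(1)[0] % 2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["grid"] = list(d["synthetic"]["grid"])
        d["preprocessing"]["normalization_region"] = list(
            d["preprocessing"]["normalization_region"]
        )
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "synthetic" in data:
            data["synthetic"] = _from_dict(synthetic.CohortConfig, dict(data["synthetic"]))
        if "preprocessing" in data:
            data["preprocessing"] = _from_dict(
                preprocessing.PreprocessConfig, dict(data["preprocessing"])
            )
        return _from_dict(cls, data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: RunConfig) -> Path:
    """Simulate, preprocess, test, decompose and classify; write every artifact.

    Deterministic under a fixed config (including seed): the summary metrics
    file is byte-identical across reruns.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- simulate ---------------------------------------------------------
    sim_cfg = dataclasses.replace(config.synthetic, seed=config.child_seed("simulate"))
    logger.info("simulate: %d male + %d female", sim_cfg.n_male, sim_cfg.n_female)
    cohort = synthetic.simulate_cohort(sim_cfg)
    write_cohort(cohort, out / "raw")

    # --- preprocess -------------------------------------------------------
    logger.info("preprocess: order-%d baseline, area normalization", config.preprocessing.poly_order)
    pre = preprocessing.preprocess_set(cohort, config.preprocessing)
    write_cohort(pre, out / "preprocessed")

    # --- stats ------------------------------------------------------------
    summary_m = band_stats.group_summary(pre, "sex", "male")
    summary_f = band_stats.group_summary(pre, "sex", "female")
    diff = band_stats.difference_spectrum(pre, "male", "female")
    profile = band_stats.pointwise_ttest(pre, "sex")
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    write_spectrum(summary_m.mean, stats_dir / "mean_male.csv")
    write_spectrum(summary_f.mean, stats_dir / "mean_female.csv")
    write_spectrum(diff, stats_dir / "difference_male_minus_female.csv")
    profile.to_frame().to_csv(stats_dir / "ttest_profile.csv", index=False)

    bands = band_stats.select_bands(profile, config.n_bands, config.min_separation_cm1)
    pairs = band_stats.select_paired_bands(profile, 2, config.min_separation_cm1)
    features = band_stats.ratio_features(pre, pairs) if pairs else None
    if features is not None:
        features.to_csv(stats_dir / "ratio_features.csv", index=False)

    # --- decompose --------------------------------------------------------
    X = pre.intensity_matrix()
    labels = pre.labels("sex")
    pca_res = chemometrics.pca(X, n_components=min(config.n_pcs_considered, len(labels) - 1))
    decomp_dir = out / "decompose"
    decomp_dir.mkdir(exist_ok=True)
    pd.DataFrame(pca_res.scores).to_csv(decomp_dir / "pca_scores.csv", index=False)
    pd.DataFrame(pca_res.loadings, columns=[f"{w:g}" for w in pre.wavenumbers]).to_csv(
        decomp_dir / "pca_loadings.csv", index=False
    )
    y = chemometrics.artificial_profile(labels)
    r2_cal, r2_val, _ = chemometrics.loocv_pls(X, y, config.n_pls_factors)

    # --- sexing -----------------------------------------------------------
    cm_pca_lda, _ = sexing.pca_lda_loocv(pre, config.n_pcs_considered)
    sex_dir = out / "sexing"
    sex_dir.mkdir(exist_ok=True)
    cm_pca_lda.to_frame().to_csv(sex_dir / "confusion_pca_lda.csv")
    metrics = {
        "n_samples": len(pre),
        "selected_bands_cm1": bands,
        "band_pairs": [list(p) for p in pairs],
        "significant_fraction": float(profile.mask.mean()),
        "discriminant_pc": int(
            sexing.select_discriminant_pc(pca_res, labels)
        ),
        "pls_r2_calibration": round(r2_cal, 4),
        "pls_r2_validation": round(r2_val, 4),
        "pca_lda_loocv_accuracy_pct": sexing.accuracy(cm_pca_lda),
    }
    if features is not None and pairs:
        pair_cols = tuple(f"R_{n:g}/{d:g}" for n, d in pairs)
        cm_ratio, _ = sexing.evaluate_classifier(features, pair_cols)
        cm_ratio.to_frame().to_csv(sex_dir / "confusion_ratio_plane.csv")
        metrics["ratio_plane_loocv_accuracy_pct"] = sexing.accuracy(cm_ratio)
    (out / "summary.json").write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
    logger.info("run complete: %s", out / "summary.json")
    return out
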