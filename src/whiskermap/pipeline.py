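"""End-to-end orchestration and condition contrasts.

``analyze_session`` runs preprocessing, trial responses, receptive fields,
column assignment, point representation, tuned fractions, pairwise
correlations and the decoder for one session.  ``compare_conditions``
contrasts two groups of analyzed sessions (e.g. enriched vs normally
housed) with permutation tests on means and Fisher's exact tests on tuned
fractions, per distance bin.  ``run_pipeline`` ties both together and
writes CSV tables plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlations as corrmod
from . import decoder as decmod
from . import somatotopy as somamod
from .io import read_session
from .preprocess import session_dff
from .responses import AnalysisWindows, build_receptive_fields, evoked_response_per_trial
from .session import WHISKERS, SessionBundle
from .stats import permutation_mean_test


@dataclass
class PipelineConfig:
    """Every tunable of the analysis; defaults are the study's values."""

    neuropil_r: float = 0.0
    alpha: float = 0.05
    n_perm: int = 10000
    evoked_window_s: tuple[float, float] = (0.0, 1.0)
    baseline_window_s: tuple[float, float] = (-0.5, 0.0)
    bin_um: float = 75.0
    corr_bin_um: float = 50.0
    decoder_bin_um: float = 77.0
    decoder_sizes: tuple = decmod.DEFAULT_SIZES
    decoder_repeats: int = 500
    ensemble_k_step: int = 1
    measure: str = "eBW"
    reference_whisker: str = "D2"
    seed: int = 0
    l4_column_filter: bool = False
    run_correlations: bool = True
    run_decoder: bool = True
    contrast_fdr: bool = False

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.neuropil_r <= 1.0:
            raise ValueError("neuropil_r must be in [0, 1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.measure not in ("BW", "eBW"):
            raise ValueError("measure must be BW or eBW")
        if self.reference_whisker not in WHISKERS:
            raise ValueError(f"bad reference whisker: {self.reference_whisker!r}")
        for name in ("bin_um", "corr_bin_um", "decoder_bin_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.windows().validate()

    def windows(self) -> AnalysisWindows:
        return AnalysisWindows(
            evoked_window_s=tuple(self.evoked_window_s),
            baseline_window_s=tuple(self.baseline_window_s),
            alpha=self.alpha,
            n_perm=self.n_perm,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("evoked_window_s", "baseline_window_s", "decoder_sizes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def analyze_session(bundle: SessionBundle, config: PipelineConfig) -> dict:
    """Run every stage on one session; returns a dict of result tables."""
    config.validate()
    windows = config.windows()
    dff, filtered = session_dff(bundle, r_weight=config.neuropil_r)
    trials = evoked_response_per_trial(dff, filtered.stimulus, windows)
    rf = build_receptive_fields(trials, windows, seed=config.seed)
    assignment = somamod.assign_columns(filtered.rois, filtered.barrels)
    coords = somamod.to_reference_frame(
        filtered.rois, filtered.barrels, config.reference_whisker
    )

    if config.l4_column_filter and bundle.layer == "L4":
        keep_cols = {"C1", "C2", "C3"}
        keep = assignment["column"].isin(keep_cols).to_numpy()
        rf = rf.copy()
        rf.loc[~keep, "is_responsive"] = False

    ref = config.reference_whisker
    coords_df = pd.DataFrame(
        {
            "roi_id": filtered.rois.roi_ids,
            "x_ref_um": coords[:, 0],
            "y_ref_um": coords[:, 1],
        }
    )
    roi_summary = rf.merge(assignment, on="roi_id").merge(coords_df, on="roi_id")
    roi_summary["dist_um"] = np.hypot(
        roi_summary["x_ref_um"], roi_summary["y_ref_um"]
    )
    roi_summary["z_ref"] = roi_summary[f"z_{ref}"]
    roi_summary["tuned_bw"] = (roi_summary["bw"] == ref).to_numpy()
    roi_summary["tuned_ebw"] = [
        (ref in s) if isinstance(s, frozenset) else False
        for s in roi_summary["ebw_set"]
    ]
    roi_summary["session_id"] = bundle.session_id
    roi_summary["condition"] = bundle.condition
    # coordinates in rf row order, for the positional-coords interfaces
    rf_coords = (
        coords_df.set_index("roi_id")
        .loc[rf["roi_id"]][["x_ref_um", "y_ref_um"]]
        .to_numpy()
    )

    results = {
        "session_id": bundle.session_id,
        "condition": bundle.condition,
        "excluded_movies": dff.excluded_movie_ids,
        "trials": trials,
        "rf": rf,
        "assignment": assignment,
        "coords": coords,
        "roi_summary": roi_summary,
        "point_representation": somamod.point_representation(
            rf, rf_coords, ref, config.bin_um
        ),
        "tuned_fractions": somamod.fraction_tuned_by_distance(
            rf, rf_coords, ref, config.measure, config.bin_um
        ),
    }

    eligible = roi_summary[
        roi_summary["is_responsive"] & (roi_summary["column"] != somamod.SEPTUM)
    ]
    if config.run_correlations and len(eligible) >= 2:
        pairs = corrmod.pairwise_table(trials, rf, assignment, coords_um=rf_coords)
        results["pair_correlations"] = pairs
        results["binned_correlations"] = corrmod.distance_binned_correlations(
            pairs, config.corr_bin_um
        )

    if config.run_decoder and len(eligible) >= 2:
        ids = eligible["roi_id"].tolist()
        evaluator = decmod.DecoderEvaluator(
            trials,
            ids,
            n_repeats=config.decoder_repeats,
            seed=config.seed,
        )
        single = pd.DataFrame(
            {
                "roi_id": ids,
                "fraction_correct": [
                    evaluator.single_roi_accuracy(r, ref) for r in ids
                ],
            }
        )
        el_coords = (
            coords_df.set_index("roi_id")
            .loc[ids][["x_ref_um", "y_ref_um"]]
            .to_numpy()
        )
        k_values = range(2, len(ids) + 1, config.ensemble_k_step)
        specs = decmod.cluster_spatial_ensembles(
            ids, el_coords, ref, seed=config.seed, k_values=k_values
        )
        for spec in specs:
            spec.fraction_correct = evaluator.ensemble_accuracy(
                list(spec.member_roi_ids), ref
            )
        results["decoder_single"] = single
        results["decoder_ensembles"] = specs
        results["decoder_distance"] = decmod.distance_binned_performance(
            specs, config.decoder_bin_um
        )
    return results


def _binned_mean_contrast(
    values_a, dist_a, values_b, dist_b, bin_width, n_perm, rng
) -> pd.DataFrame:
    """Per-bin two-sided permutation contrast of two groups of per-item values."""
    values_a, dist_a = np.asarray(values_a, float), np.asarray(dist_a, float)
    values_b, dist_b = np.asarray(values_b, float), np.asarray(dist_b, float)
    n_bins = int(
        max(
            np.floor(dist_a.max() / bin_width) if dist_a.size else 0,
            np.floor(dist_b.max() / bin_width) if dist_b.size else 0,
        )
        + 1
    )
    rows = []
    for b in range(n_bins):
        va = values_a[(dist_a >= b * bin_width) & (dist_a < (b + 1) * bin_width)]
        vb = values_b[(dist_b >= b * bin_width) & (dist_b < (b + 1) * bin_width)]
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        row = {
            "bin_lo_um": b * bin_width,
            "bin_hi_um": (b + 1) * bin_width,
            "mean_a": va.mean() if va.size else np.nan,
            "mean_b": vb.mean() if vb.size else np.nan,
            "n_a": int(va.size),
            "n_b": int(vb.size),
        }
        if va.size >= 2 and vb.size >= 2:
            row["p"] = permutation_mean_test(
                va, vb, n_perm=n_perm, alternative="two_sided", rng=rng
            )
        else:
            row["p"] = np.nan  # contrast skipped: empty or degenerate bin
        rows.append(row)
    return pd.DataFrame(rows)


def compare_conditions(
    group_a: list[dict], group_b: list[dict], config: PipelineConfig
) -> dict:
    """Contrast two groups of analyzed sessions (A vs B).

    Returns per-bin point-representation and decoder contrasts (two-sided
    permutation tests), per-bin tuned-fraction contrasts (Fisher's exact),
    and within/across-column correlation contrasts.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(config.seed)
    roi_a = pd.concat([g["roi_summary"] for g in group_a], ignore_index=True)
    roi_b = pd.concat([g["roi_summary"] for g in group_b], ignore_index=True)
    resp_a = roi_a[roi_a["is_responsive"]]
    resp_b = roi_b[roi_b["is_responsive"]]

    out: dict = {}
    out["point_representation"] = _binned_mean_contrast(
        resp_a["z_ref"], resp_a["dist_um"],
        resp_b["z_ref"], resp_b["dist_um"],
        config.bin_um, config.n_perm, rng,
    )

    tuned_col = "tuned_ebw" if config.measure == "eBW" else "tuned_bw"
    rows = []
    n_bins = int(
        np.floor(
            max(resp_a["dist_um"].max(), resp_b["dist_um"].max()) / config.bin_um
        )
        + 1
    )
    for b in range(n_bins):
        lo, hi = b * config.bin_um, (b + 1) * config.bin_um
        sa = resp_a[(resp_a["dist_um"] >= lo) & (resp_a["dist_um"] < hi)]
        sb = resp_b[(resp_b["dist_um"] >= lo) & (resp_b["dist_um"] < hi)]
        row = {
            "bin_lo_um": lo,
            "bin_hi_um": hi,
            "tuned_a": int(sa[tuned_col].sum()),
            "n_a": len(sa),
            "tuned_b": int(sb[tuned_col].sum()),
            "n_b": len(sb),
        }
        if len(sa) and len(sb):
            _, row["p"] = somamod.compare_tuned_fractions(
                int(sa[tuned_col].sum()), len(sa),
                int(sb[tuned_col].sum()), len(sb),
            )
            row["fraction_a"] = sa[tuned_col].mean()
            row["fraction_b"] = sb[tuned_col].mean()
        else:
            row["p"] = np.nan
            row["fraction_a"] = np.nan
            row["fraction_b"] = np.nan
        rows.append(row)
    out["tuned_fractions"] = pd.DataFrame(rows)

    if all("pair_correlations" in g for g in group_a + group_b):
        pa = pd.concat([g["pair_correlations"] for g in group_a], ignore_index=True)
        pb = pd.concat([g["pair_correlations"] for g in group_b], ignore_index=True)
        rows = []
        for rel in ("within_column", "across_column"):
            for kind in ("signal_corr", "noise_corr"):
                va = pa.loc[pa["relation"] == rel, kind].dropna().to_numpy()
                vb = pb.loc[pb["relation"] == rel, kind].dropna().to_numpy()
                row = {
                    "relation": rel,
                    "kind": kind,
                    "mean_a": va.mean() if va.size else np.nan,
                    "mean_b": vb.mean() if vb.size else np.nan,
                    "n_a": int(va.size),
                    "n_b": int(vb.size),
                    "p": permutation_mean_test(
                        va, vb, n_perm=config.n_perm,
                        alternative="two_sided", rng=rng,
                    )
                    if va.size >= 2 and vb.size >= 2
                    else np.nan,
                }
                rows.append(row)
        out["correlations"] = pd.DataFrame(rows)

    if all("decoder_ensembles" in g for g in group_a + group_b):
        da = [
            (e.distance_to_reference_um, e.fraction_correct)
            for g in group_a
            for e in g["decoder_ensembles"]
        ]
        db = [
            (e.distance_to_reference_um, e.fraction_correct)
            for g in group_b
            for e in g["decoder_ensembles"]
        ]
        out["decoder"] = _binned_mean_contrast(
            [a for _, a in da], [d for d, _ in da],
            [a for _, a in db], [d for d, _ in db],
            config.decoder_bin_um, config.n_perm, rng,
        )

    if config.contrast_fdr:
        from .stats import fdr_bh

        for key in ("point_representation", "tuned_fractions", "decoder"):
            if key in out:
                t = out[key]
                ok = t["p"].notna()
                t.loc[ok, "p_fdr"] = fdr_bh(t.loc[ok, "p"].to_numpy())
    return out


def _write_tables(results: dict, out_dir: Path) -> list[str]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, val in results.items():
        if isinstance(val, pd.DataFrame):
            path = out_dir / f"{key}.csv"
            flat = val.copy()
            for col in flat.columns:
                if flat[col].map(lambda v: isinstance(v, frozenset)).any():
                    flat[col] = flat[col].map(
                        lambda s: "|".join(sorted(s)) if isinstance(s, frozenset) else ""
                    )
            flat.to_csv(path, index=False)
            written.append(str(path))
    return written


def run_pipeline(config: PipelineConfig, sessions, out_dir) -> dict:
    """Analyze each session, contrast conditions, and write a report directory.

    ``sessions`` is a list of session directories or in-memory bundles.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = []
    written = []
    for s in sessions:
        bundle = s if isinstance(s, SessionBundle) else read_session(s)
        try:
            res = analyze_session(bundle, config)
        except Exception as err:
            raise RuntimeError(
                f"stage failure in session {bundle.session_id}: {err}"
            ) from err
        results.append(res)
        sess_dir = out / bundle.session_id
        written += _write_tables(
            {k: v for k, v in res.items() if isinstance(v, pd.DataFrame)}, sess_dir
        )

    conditions = sorted({r["condition"] for r in results})
    contrast = None
    if len(conditions) == 2:
        group_a = [r for r in results if r["condition"] == conditions[0]]
        group_b = [r for r in results if r["condition"] == conditions[1]]
        contrast = compare_conditions(group_a, group_b, config)
        written += _write_tables(contrast, out / "contrast")

    cfg_dict = asdict(config)
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "sessions": [r["session_id"] for r in results],
        "conditions": conditions,
        "contrast_order": conditions if contrast is not None else None,
        "tables": sorted(written),
        "excluded_movies": {
            r["session_id"]: r["excluded_movies"] for r in results
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"sessions": results, "contrast": contrast, "manifest": manifest}
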