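"""End-to-end orchestration: simulate -> preprocess -> TFR -> stats -> clusters.

The default analysis matches the study design: the INT factor is tested
stimulus-locked 0-1.6 s; EXP cue-locked 0-3.6 s; the absolute, signed
and one-sided prediction errors stimulus-locked 0-1.6 s; each factor in
the low (1-30 Hz, Hanning) and high (31-100 Hz, multitaper) bands with
1000 within-subject permutations at a cluster-forming threshold of
F(1, n-1) at alpha = 0.05.  Grid resolutions, channel subsets, subject
counts and permutation counts are configurable so the same pipeline
runs at reduced scale.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import montage
from .cluster import ClusterTest, permutation_test
from .design import Trial, heat_cells
from .preprocess import EpochSet, relock, rereference_common_average
from .rm_stats import ConditionAverage, behavioral_anova
from .simulate import SyntheticConfig, simulate_study
from .tfr import BaselineSpec, average_by_condition, tfr_hanning, tfr_multitaper, zbaseline

__all__ = ["FactorSpec", "AnalysisConfig", "run", "report_clusters", "compute_condition_averages"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FactorSpec:
    """Lock mode and analysis window of one factor."""

    factor: str
    lock: str
    window: tuple[float, float]


def default_factor_specs() -> tuple[FactorSpec, ...]:
    return (
        FactorSpec("INT", "stimulus", (0.0, 1.6)),
        FactorSpec("EXP", "cue", (0.0, 3.6)),
        FactorSpec("PE", "stimulus", (0.0, 1.6)),
        FactorSpec("signedPE", "stimulus", (0.0, 1.6)),
        FactorSpec("onesidedPE", "stimulus", (0.0, 1.6)),
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the statistical analysis."""

    model: str = "full"
    factors: tuple[FactorSpec, ...] = field(default_factory=default_factor_specs)
    bands: tuple[str, ...] = ("low", "high")
    low_freqs: tuple[float, ...] | None = None  # None -> 1..30 Hz, 1 Hz grid
    high_freqs: tuple[float, ...] | None = None  # None -> 31..100 Hz, 1 Hz grid
    time_step: float = 0.05
    n_perm: int = 1000
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    baseline_cue: tuple[float, float] = BaselineSpec.CUE_DEFAULT
    baseline_stimulus: tuple[float, float] = BaselineSpec.STIMULUS_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        for spec in self.factors:
            if spec.lock not in ("cue", "stimulus"):
                raise ValueError(f"factor {spec.factor}: unknown lock {spec.lock!r}")
            if spec.window[0] >= spec.window[1]:
                raise ValueError(f"factor {spec.factor}: empty window {spec.window}")

    def replace(self, **changes) -> "AnalysisConfig":
        return replace(self, **changes)

    def baseline(self, lock: str) -> BaselineSpec:
        return BaselineSpec(self.baseline_cue if lock == "cue" else self.baseline_stimulus)

    def band_freqs(self, band: str) -> np.ndarray:
        if band == "low":
            return np.asarray(self.low_freqs, float) if self.low_freqs else np.arange(1.0, 31.0)
        if band == "high":
            return np.asarray(self.high_freqs, float) if self.high_freqs else np.arange(31.0, 101.0)
        raise ValueError(f"unknown band {band!r}")


def config_hash(analysis: AnalysisConfig, synth: SyntheticConfig | None = None) -> str:
    """Stable short hash of the configuration (provenance stamp)."""

    def encode(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: encode(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    blob = json.dumps({"analysis": encode(analysis), "synthetic": encode(synth)},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _time_grid(window: tuple[float, float], step: float) -> np.ndarray:
    n = int(round((window[1] - window[0]) / step))
    return np.round(window[0] + step * np.arange(n + 1), 9)


def _analysis_times(config: AnalysisConfig, lock: str) -> np.ndarray:
    """Union of the baseline grid and all factor windows for one lock mode."""
    grids = [_time_grid(config.baseline(lock).window, config.time_step)]
    for spec in config.factors:
        if spec.lock == lock:
            grids.append(_time_grid(spec.window, config.time_step))
    return np.unique(np.round(np.concatenate(grids), 9))


def compute_condition_averages(
    epochs_per_subject: list[EpochSet], config: AnalysisConfig
) -> dict[tuple[str, str], ConditionAverage]:
    """Per (lock, band): subjects x cells x channels x freqs x times z power.

    Per subject: common-average re-reference, re-lock, sliding-window
    decomposition on the union of the baseline and analysis windows,
    trial averaging per condition cell, and z-baseline normalization.
    """
    cells = heat_cells(config.model)
    locks = sorted({spec.lock for spec in config.factors})
    stacks: dict[tuple[str, str], list[np.ndarray]] = {
        (lock, band): [] for lock in locks for band in config.bands
    }
    meta: dict[tuple[str, str], dict] = {}
    for s, ep in enumerate(epochs_per_subject):
        ep = rereference_common_average(ep)
        for lock in locks:
            locked = relock(ep, lock)
            times = _analysis_times(config, lock)
            for band in config.bands:
                freqs = config.band_freqs(band)
                if band == "low":
                    tfr = tfr_hanning(locked, freqs=freqs, times=times, step=config.time_step)
                else:
                    tfr = tfr_multitaper(locked, freqs=freqs, times=times, step=config.time_step)
                avg = average_by_condition(tfr, cells)
                z = zbaseline(avg, config.baseline(lock))
                stacks[(lock, band)].append(z.power)
                meta[(lock, band)] = {
                    "ch_names": z.ch_names, "freqs": z.freqs, "times": z.times,
                }
        logger.info("subject %d: condition averages over %d cells (%s model)",
                    s, len(cells), config.model)
    return {
        key: ConditionAverage(
            z=np.stack(powers), cells=cells, model=config.model, **meta[key]
        )
        for key, powers in stacks.items()
    }


def run(
    analysis: AnalysisConfig,
    synth: SyntheticConfig | None = None,
    epochs_per_subject: list[EpochSet] | None = None,
    ratings: pd.DataFrame | None = None,
    design: list[Trial] | None = None,
    out_dir: str | Path | None = None,
    neighbors: montage.ChannelNeighborhood | None = None,
) -> dict:
    """Run the full analysis and return (optionally write) a report bundle.

    Inputs are either a :class:`SyntheticConfig` (data are simulated) or
    ready per-subject epoch sets plus a trial-level rating table.
    """
    if synth is not None:
        design, epochs_per_subject, ratings = simulate_study(synth, design=design)
    if not epochs_per_subject:
        raise ValueError("no input data: pass synth= or epochs_per_subject=")

    if neighbors is None:
        neighbors = montage.default_neighborhood()
    averages = compute_condition_averages(epochs_per_subject, analysis)

    eeg_tests: dict[str, ClusterTest] = {}
    for k, spec in enumerate(sorted(analysis.factors, key=lambda s: s.factor)):
        for band in analysis.bands:
            avg = averages[(spec.lock, band)]
            freqs = analysis.band_freqs(band)
            test = permutation_test(
                avg, spec.factor, neighbors,
                n_perm=analysis.n_perm,
                seed=[analysis.seed, 4099, k, 0 if band == "low" else 1],
                cluster_alpha=analysis.cluster_alpha,
                window=spec.window,
                band=(freqs.min(), freqs.max()),
            )
            eeg_tests[f"{spec.factor}_{band}"] = test
            logger.info("%s %s-band (%s-locked): %d clusters, min p %s",
                        spec.factor, band, spec.lock, len(test.clusters),
                        min((c.p for c in test.clusters), default=None))

    behavioral = None
    if ratings is not None:
        behavioral = behavioral_anova(ratings, model=analysis.model)

    bundle = {
        "config_hash": config_hash(analysis, synth),
        "seed": analysis.seed,
        "model": analysis.model,
        "n_subjects": len(epochs_per_subject),
        "eeg_tests": eeg_tests,
        "behavioral": behavioral,
        "analysis": analysis,
    }
    if out_dir is not None:
        _write_bundle(Path(out_dir), bundle)
    return bundle


def _clusters_json(eeg_tests: dict[str, ClusterTest]) -> dict:
    return {
        name: {
            "factor": t.factor,
            "threshold": t.threshold,
            "df": list(t.df),
            "n_perm": t.n_perm,
            "clusters": [c.summary() for c in t.clusters],
        }
        for name, t in eeg_tests.items()
    }


def _write_bundle(out_dir: Path, bundle: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = _clusters_json(bundle["eeg_tests"])
    (out_dir / "clusters.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
    rows = []
    for name, t in bundle["eeg_tests"].items():
        for c in t.clusters:
            s = c.summary()
            rows.append({
                "test": name, "sign": s["sign"], "mass": s["mass"], "p": s["p"],
                "n_samples": s["n_samples"],
                "t_min": s["time_range_s"][0], "t_max": s["time_range_s"][1],
                "f_min": s["freq_range_hz"][0], "f_max": s["freq_range_hz"][1],
                "n_channels": s["n_channels"],
                "peak_channel": s["peak"]["channel"], "peak_F": s["peak"]["F"],
            })
    pd.DataFrame(rows).to_csv(out_dir / "clusters.csv", index=False)
    if bundle["behavioral"] is not None:
        bundle["behavioral"].to_csv(out_dir / "behavioral.csv", index=False)
    (out_dir / "report.txt").write_text(report_clusters(bundle))
    stamp = {"config_hash": bundle["config_hash"], "seed": bundle["seed"],
             "model": bundle["model"], "n_subjects": bundle["n_subjects"]}
    (out_dir / "run.json").write_text(json.dumps(stamp, indent=1, sort_keys=True))


def report_clusters(bundle: dict, alpha: float = 0.05) -> str:
    """Human-readable summary of every test's clusters."""
    lines = [
        f"cuedpain analysis report (model={bundle['model']}, "
        f"n={bundle['n_subjects']}, seed={bundle['seed']}, "
        f"config={bundle['config_hash']})",
        "",
    ]
    for name, t in bundle["eeg_tests"].items():
        lines.append(f"[{name}] threshold F({t.df[0]},{t.df[1]}) > {t.threshold:.3f}, "
                     f"{t.n_perm} permutations")
        if not t.clusters:
            lines.append("  no clusters formed")
        for c in t.clusters:
            tag = "*" if (c.p is not None and c.p <= alpha) else " "
            t0, t1 = c.time_range
            f0, f1 = c.freq_range
            lines.append(
                f" {tag} {'positive' if c.sign > 0 else 'negative'} cluster: "
                f"p={c.p:.4f}, mass={c.mass:.1f}, {c.n_members} samples, "
                f"{t0:.2f}-{t1:.2f} s, {f0:.0f}-{f1:.0f} Hz, "
                f"{len(c.channels)} channels, peak {c.peak['channel']} "
                f"(F={c.peak['F']:.2f} at {c.peak['time_s']:.2f} s, "
                f"{c.peak['freq_hz']:.0f} Hz)"
            )
        lines.append("")
    if bundle.get("behavioral") is not None:
        lines.append("behavioral rm-ANOVA (ratings):")
        for _, r in bundle["behavioral"].iterrows():
            lines.append(
                f"  {r['factor']}: F({int(r['df1'])},{int(r['df2'])}) = {r['F']:.2f}, "
                f"p = {r['p']:.2g}"
            )
        lines.append("")
    sig = sum(
        1 for t in bundle["eeg_tests"].values()
        for c in t.clusters if c.p is not None and c.p <= alpha
    )
    if sig == 0:
        lines.append("no significant clusters")
    else:
        lines.append(f"{sig} significant cluster(s) at alpha={alpha}")
    return "\n".join(lines)
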