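"""Pipeline driver: simulate -> process -> normalize -> analyze -> report.

Each stage reads and writes the CSV interchange formats of :mod:`.io`, so
stages can be re-run individually (the command-line interface wraps exactly
these functions).  A fixed seed makes every stage byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as lio
from . import kinematics as kin
from . import metrics, normalize, stats, synth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "process", "normalize", "analyze", "report")


def process_condition(
    traces: Mapping[str, kin.SensorTrace],
    min_strides: int = kin.DEFAULT_MIN_STRIDES,
    use_truth_attribution: bool = False,
    **labels: str,
) -> dict[str, object]:
    """Raw five-landmark traces -> one condition-level asymmetry record.

    Rotates each trace to the horse frame, double-integrates to vertical
    displacement, segments strides on the sacrum signal, attributes steps to
    hind stances from the tuber coxae phase (or from the synthetic
    ground-truth labels when requested), extracts per-stride features and
    summarises the 11 indices by their medians.
    """
    missing = [lm for lm in kin.LANDMARKS if lm not in traces]
    if missing:
        raise ValueError(f"missing landmark traces: {', '.join(missing)}")

    displacements: dict[str, np.ndarray] = {}
    for lm, trace in traces.items():
        acc_z = kin.rotate_to_horse_frame(trace)
        step_period = kin.estimate_step_period(acc_z, trace.sample_rate)
        stride_freq = 1.0 / (2.0 * step_period)
        displacements[lm] = kin.integrate_to_displacement(
            acc_z, trace.sample_rate, stride_freq
        )

    fs = traces["sacrum"].sample_rate
    # the high-pass/integration cascade leaves edge transients that decay
    # over a few strides; the outermost strides are discarded before
    # feature extraction
    strides = kin.segment_strides(displacements["sacrum"], fs, min_strides=min_strides)
    strides = kin.trim_strides(strides, 3)

    if use_truth_attribution:
        truth = traces["sacrum"].truth
        if truth is None:
            raise ValueError("use_truth_attribution requires synthetic traces")
        attribution = truth.stance_labels
    else:
        attribution = kin.attribute_steps(
            displacements["left_tuber_coxae"],
            displacements["right_tuber_coxae"],
            strides,
        )

    features, n_dropped = kin.extract_stride_features(
        displacements, strides, attribution, fs
    )
    indices = metrics.stride_indices_table(features)
    record = metrics.condition_summary(
        indices, strides.stride_times, min_strides=min_strides, **labels
    )
    logger.info(
        "condition %s: %d strides retained, %d discarded, %d dropped at extraction",
        labels, record["n_strides"], strides.n_discarded, n_dropped,
    )
    return record


def _study_trot_params(config: lio.StudyConfig, effects: synth.StudyEffects,
                       rng: np.random.Generator) -> dict:
    """Per-horse latent asymmetry draws for the signal-level study."""
    params = list(effects.baseline.keys())
    horses = {}
    for h in range(config.n_horses):
        horse = f"H{h + 1:02d}"
        intercepts = {p: rng.normal(0.0, effects.horse_sd) for p in params}
        sides = {p: 1.0 if rng.random() < effects.side_prob else -1.0 for p in params}
        horses[horse] = (intercepts, sides)
    return horses


def simulate_stage(config: lio.StudyConfig, seed: int, out_dir: Path) -> Path:
    """Write synthetic five-landmark trace sets for a small signal-level study.

    For each horse and condition the latent condition-level asymmetries are
    drawn from the study model and injected into the trot waveform
    generator; the measurement noise of the traces plays the role of the
    residual.  Traces and ground-truth side-cars go to
    ``out_dir/signals/<horse>/<surface>_<speed>_<direction>/``.
    """
    signals = Path(out_dir) / "signals"
    signals.mkdir(parents=True, exist_ok=True)
    effects = synth.StudyEffects(
        n_horses=config.n_horses,
        radius=config.circle_radius,
        lean_gain=config.lean_gain,
        slow_speed=config.slow_speed,
        fast_speed=config.fast_speed,
        residual_sd=0.0,  # residual variation comes from the trace noise
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    horses = _study_trot_params(config, effects, rng)
    cond_seed = 0
    for horse, (intercepts, sides) in horses.items():
        for surface, speed, direction in effects.conditions:
            cond_seed += 1
            raw = {
                p: sides[p]
                * (
                    effects.baseline[p]
                    + intercepts[p]
                    + (effects.surface_effect if surface == "hard" else 0.0)
                )
                for p in effects.baseline
            }
            params = synth.TrotParams(
                stride_time=config.stride_time,
                asym_min={"poll": raw["HDmin"], "withers": raw["WDmin"], "sacrum": raw["PDmin"]},
                asym_max={"poll": raw["HDmax"], "withers": raw["WDmax"], "sacrum": raw["PDmax"]},
                hike_diff=raw["HHD"],
                rom_diff=raw["RD"],
                noise_sd=config.noise_sd,
                sample_rate=config.sample_rate,
                duration=config.duration,
                stride_time_jitter=0.05,
            )
            circle = None
            if direction != "straight":
                circle = synth.CircleParams(
                    speed=effects.condition_speed(speed),
                    radius=config.circle_radius,
                    lean_gain=config.lean_gain,
                    direction=direction,
                )
            traces = synth.simulate_condition(params, seed=1000 * seed + cond_seed, circle=circle)
            cdir = signals / horse / f"{surface}_{speed}_{direction}"
            cdir.mkdir(parents=True, exist_ok=True)
            for lm, trace in traces.items():
                lio.write_sensor_trace(trace, cdir / f"{lm}.csv")
            lio.write_truth_sidecar(traces["sacrum"].truth, cdir / "truth.yaml")
    logger.info("simulate: wrote %d condition trace sets", cond_seed)
    return signals


def process_stage(config: lio.StudyConfig, out_dir: Path) -> Path:
    """Process all simulated/recorded trace sets into a condition table."""
    signals = Path(out_dir) / "signals"
    if not signals.exists():
        raise ValueError("process stage requires the simulate stage outputs (signals/)")
    records = []
    for horse_dir in sorted(signals.iterdir()):
        if not horse_dir.is_dir():
            continue
        for cond_dir in sorted(horse_dir.iterdir()):
            surface, speed, direction = cond_dir.name.split("_")
            traces = lio.read_sensor_traces(cond_dir, sample_rate=config.sample_rate)
            record = process_condition(
                traces,
                min_strides=config.min_strides,
                horse=horse_dir.name,
                surface=surface,
                speed=speed,
                direction=direction,
            )
            records.append(record)
    table = pd.DataFrame(records)
    out = Path(out_dir) / "conditions.csv"
    lio.write_condition_table(table, out)
    logger.info("process: wrote %d condition records", len(table))
    return out


def normalize_stage(out_dir: Path) -> Path:
    """Normalize the condition table and write the long normalized table."""
    cond_path = Path(out_dir) / "conditions.csv"
    if not cond_path.exists():
        raise ValueError("normalize stage requires the process stage output (conditions.csv)")
    records = lio.read_condition_table(cond_path)
    norm = normalize.normalize_dataset(records)
    out = Path(out_dir) / "normalized.csv"
    lio.write_normalized_table(norm.records, out)
    logger.info(
        "normalize: %d rows, %d unmatched rein conditions excluded from averaging",
        len(norm.records), norm.n_unmatched,
    )
    return out


def analyze_stage(out_dir: Path) -> Path:
    """Run the statistics chain, writing result tables as CSV."""
    cond_path = Path(out_dir) / "conditions.csv"
    norm_path = Path(out_dir) / "normalized.csv"
    if not norm_path.exists():
        raise ValueError("analyze stage requires the normalize stage output (normalized.csv)")
    records = lio.read_condition_table(cond_path)
    long = lio.read_normalized_table(norm_path)
    signs = normalize.compute_signs(records)
    norm = normalize.NormalizedDataset(
        records=long, signs=signs,
        side_labels=normalize.side_labels_from_signs(signs),
    )
    analysis = stats.run_full_analysis(records, norm=norm)
    adir = Path(out_dir) / "analysis"
    adir.mkdir(exist_ok=True)
    analysis.table1.to_csv(adir / "descriptives.csv")
    analysis.trends.to_csv(adir / "trend_lines.csv")
    analysis.agreement.to_csv(adir / "limits_of_agreement.csv")
    analysis.straight_vs_average.to_csv(adir / "models_straight_vs_average.csv")
    analysis.individual_rein.to_csv(adir / "models_individual_rein.csv")
    analysis.stride_time_pairwise.to_csv(adir / "stride_time_pairwise.csv", index=False)
    st = analysis.stride_time
    summary = {
        "stride_time_p": st.p_values,
        "stride_time_emm": st.emms,
        "stride_time_converged": st.converged,
        "speed_significant": dict(
            zip(
                ("individual_rein", "average_rein"),
                stats.count_speed_significant(
                    analysis.individual_rein, analysis.straight_vs_average
                ),
            )
        ),
    }
    with open(adir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("analyze: wrote result tables to %s", adir)
    return adir


def report_stage(out_dir: Path) -> Path:
    """Human-readable report plus residual histograms for each model."""
    adir = Path(out_dir) / "analysis"
    if not adir.exists():
        raise ValueError("report stage requires the analyze stage outputs (analysis/)")
    cond_path = Path(out_dir) / "conditions.csv"
    records = lio.read_condition_table(cond_path)
    norm = normalize.normalize_dataset(records)
    analysis = stats.run_full_analysis(records, norm=norm)

    lines = ["Movement asymmetry study report", "=" * 34, ""]
    lines.append(f"Horses: {records['horse'].nunique()}, records: {len(records)}")
    n_indiv, n_avg = stats.count_speed_significant(
        analysis.individual_rein, analysis.straight_vs_average
    )
    st = analysis.stride_time
    lines.append("")
    lines.append("Stride time model (ms):")
    for f, p in st.p_values.items():
        emm = ", ".join(f"{lv}={v:.0f}" for lv, v in st.emms[f].items())
        lines.append(f"  {f}: p={p:.4g}; EMM {emm}")
    lines.append("")
    lines.append(
        f"Speed-affected parameters: {n_indiv} on individual reins, "
        f"{n_avg} on the average rein"
    )
    lines.append("")
    lines.append("Limits of agreement (straight vs average rein), mm:")
    for p, row in analysis.agreement.iterrows():
        lines.append(
            f"  {p}: bias {row['mean']:+.1f}, SD {row['sd']:.1f}, 2SD {row['two_sd']:.1f}"
        )
    report = Path(out_dir) / "report.txt"
    report.write_text("\n".join(lines) + "\n")

    stats.residual_histogram(analysis.stride_time, adir / "residuals_stride_time.png")
    logger.info("report: wrote %s", report)
    return report


def run_pipeline(
    config: lio.StudyConfig,
    stages: tuple[str, ...] = STAGES,
    seed: int | None = None,
    out_dir: str | Path = "lungesym_out",
) -> Path:
    """Execute the requested stages in order; deterministic given the seed."""
    seed = config.seed if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; stages: {', '.join(STAGES)}")
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("running stage: %s", stage)
        if stage == "simulate":
            simulate_stage(config, seed, out_dir)
        elif stage == "process":
            process_stage(config, out_dir)
        elif stage == "normalize":
            normalize_stage(out_dir)
        elif stage == "analyze":
            analyze_stage(out_dir)
        elif stage == "report":
            report_stage(out_dir)
    return out_dir
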