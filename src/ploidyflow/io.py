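"""Readers, writers, configuration and pipeline orchestration.

Event lists travel as two-column CSV (``intensity``, optional
``true_label``) or as a minimal single-parameter FCS 3.1 file.  The
pipeline runs the full analysis order — simulate (or load) acquisitions,
gate, estimate genome size, profile endopolyploidy, compute the
statistics layer — and writes table-shaped reports plus a QC log.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import datasets
from ._utils import round_half_up
from .endopolyploidy import profile_from_events
from .gating import (
    DEFAULT_MAX_CV_PERCENT,
    autoscale_gain,
    build_histogram,
    detect_peaks,
    gate_peak,
    qc_cv,
)
from .genome_size import (
    STANDARDS,
    complete_estimate,
    estimate_two_c,
    summarize_replicates,
)
from .karyostats import (
    boxcox_chromosome_transform,
    one_way_anova,
    pearson_with_regression,
    series_group_means,
    tukey_kramer,
)
from .simulate import (
    AcquisitionConfig,
    EventSample,
    SpeciesTruth,
    simulate_mixed_run,
    simulate_nuclei_events,
)

# ---------------------------------------------------------------------------
# event I/O


def write_events_csv(events: EventSample, path) -> None:
    df = pd.DataFrame({"intensity": events.intensities})
    if events.true_label is not None:
        df["true_label"] = events.true_label
    df.to_csv(path, index=False, float_format="%.10g")


def read_events(path, format: Optional[str] = None) -> EventSample:
    """Load an event list from CSV or FCS (format inferred from suffix).

    Negative intensities are rejected; their count is reported in the
    sample metadata under ``n_negative_rejected``.
    """
    path = Path(path)
    fmt = format or ("fcs" if path.suffix.lower() == ".fcs" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path)
        if "intensity" not in df.columns:
            raise ValueError(f"{path}: missing 'intensity' column")
        values = df["intensity"].to_numpy(dtype=float)
        labels = (
            df["true_label"].to_numpy(dtype=object)
            if "true_label" in df.columns
            else None
        )
    elif fmt == "fcs":
        values = read_fcs(path)
        labels = None
    else:
        raise ValueError(f"unknown event format: {fmt}")
    negative = values < 0
    n_neg = int(negative.sum())
    if n_neg:
        keep = ~negative
        values = values[keep]
        labels = labels[keep] if labels is not None else None
    if len(values) == 0:
        raise ValueError(f"{path}: no usable events")
    return EventSample(
        values, labels, metadata={"path": str(path), "n_negative_rejected": n_neg}
    )


def write_fcs(events: EventSample, path) -> None:
    """Write a minimal single-parameter FCS 3.1 file (float32 data)."""
    values = events.intensities.astype("<f4")
    data = values.tobytes()
    tot = len(values)
    p1r = int(np.ceil(float(values.max()))) + 1 if tot else 1
    header_len = 58  # "FCS3.1    " + 6 eight-byte offset fields
    # fixed-width begin/end data offsets so the text can be built in one pass
    keys = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$NEXTDATA": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": "1",
        "$TOT": str(tot),
        "$P1N": "FL1",
        "$P1S": "fluorescence",
        "$P1B": "32",
        "$P1E": "0,0",
        "$P1R": str(p1r),
        "$BEGINDATA": "0" * 10,  # 10-digit placeholders, patched below
        "$ENDDATA": "0" * 10,
    }
    text = "/" + "/".join(f"{k}/{v}" for k, v in keys.items()) + "/"
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_start + len(text)
    data_end = data_start + len(data) - 1
    text = text.replace(
        f"$BEGINDATA/{'0' * 10}", f"$BEGINDATA/{data_start:010d}"
    ).replace(f"$ENDDATA/{'0' * 10}", f"$ENDDATA/{data_end:010d}")
    header = (
        b"FCS3.1    "
        + f"{text_start:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_start:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("ascii"))
        fh.write(data)


def read_fcs(path) -> np.ndarray:
    """Read the first parameter of a single-dataset FCS 3.0/3.1 file."""
    raw = Path(path).read_bytes()
    if not raw[:3] == b"FCS":
        raise ValueError(f"{path}: not an FCS file")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    kv = {
        parts[i].strip().upper(): parts[i + 1]
        for i in range(0, len(parts) - 1, 2)
    }
    if kv.get("$DATATYPE") != "F" or kv.get("$PAR") != "1":
        raise ValueError(f"{path}: only single-parameter float data supported")
    tot = int(kv["$TOT"])
    data_start = int(kv["$BEGINDATA"])
    data_end = int(kv["$ENDDATA"])
    endian = "<" if kv.get("$BYTEORD", "1,2,3,4").startswith("1") else ">"
    payload = raw[data_start : data_end + 1]
    values = struct.unpack(f"{endian}{tot}f", payload[: 4 * tot])
    return np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SpeciesSpec:
    """One species entry of a pipeline run."""

    name: str
    two_c_pg: float
    ploidy_multiplier: int = 2
    standard: str = "tomato"
    c_level_fractions: dict = field(default_factory=lambda: {"2C": 1.0})
    replicates: int = 3
    accession: str = ""


@dataclass
class PipelineConfig:
    """Validated settings of an end-to-end run; unknown keys rejected."""

    species: list[SpeciesSpec]
    output_dir: str = "ploidyflow_out"
    rng_seed: int = 0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    max_cv_percent: float = DEFAULT_MAX_CV_PERCENT
    level_tolerance: float = 0.25
    min_fraction_percent: float = 0.0
    run_statistics: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "acquisition" in raw and isinstance(raw["acquisition"], dict):
            acq = dict(raw["acquisition"])
            acq_known = {f.name for f in dataclasses.fields(AcquisitionConfig)}
            bad = set(acq) - acq_known
            if bad:
                raise ValueError(f"unknown acquisition keys: {sorted(bad)}")
            raw["acquisition"] = AcquisitionConfig(**acq)
        species = []
        for entry in raw.get("species", []):
            if isinstance(entry, dict):
                sp_known = {f.name for f in dataclasses.fields(SpeciesSpec)}
                bad = set(entry) - sp_known
                if bad:
                    raise ValueError(f"unknown species keys: {sorted(bad)}")
                species.append(SpeciesSpec(**entry))
            else:
                species.append(entry)
        raw["species"] = species
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# pipeline stages


def _gate_mixed_run(events: EventSample, spec: SpeciesSpec, anchor: float):
    """Locate and gate the sample-2C and standard-G1 peaks of one run."""
    std = STANDARDS[spec.standard]
    expected_sample = anchor
    expected_standard = anchor * std.two_c_pg / spec.two_c_pg
    scaled = autoscale_gain(events, expected_sample, 50, 250)
    factor = scaled.metadata["gain_factor"]
    hist = build_histogram(scaled, "linear", 250, upper=250.0)
    positions = detect_peaks(hist)
    if not positions:
        raise RuntimeError(f"{spec.name}: no peaks detected")
    sample_pos = min(
        positions, key=lambda p: abs(p - expected_sample * factor)
    )
    standard_pos = min(
        positions, key=lambda p: abs(p - expected_standard * factor)
    )
    if sample_pos == standard_pos:
        # peaks too close for blind detection: gate at expected positions
        sample_pos = expected_sample * factor
        standard_pos = expected_standard * factor
    # clip both gates at the midpoint between the peaks, as an operator
    # would place a manual gate in the valley
    mid = 0.5 * (sample_pos + standard_pos)
    lo, hi = (0.0, float("inf"))
    s_bounds = (lo, mid) if sample_pos < standard_pos else (mid, hi)
    t_bounds = (mid, hi) if sample_pos < standard_pos else (lo, mid)
    sample_peak = gate_peak(
        scaled, sample_pos, label="sample-2C", bounds=s_bounds
    )
    standard_peak = gate_peak(
        scaled, standard_pos, label="standard-G1", bounds=t_bounds
    )
    return sample_peak, standard_peak, std


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis for every configured species.

    Deterministic under a fixed seed: per-species, per-replicate seeds are
    derived from ``config.rng_seed``.  Returns a bundle of DataFrames and
    the statistics report; writes CSV/JSON reports into
    ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    qc_log: list[dict] = []
    gs_rows = []
    endo_rows = []

    for s_idx, spec in enumerate(config.species):
        truth = SpeciesTruth(spec.name, spec.two_c_pg, spec.c_level_fractions)
        std = STANDARDS[spec.standard]
        std_truth = SpeciesTruth(std.name, std.two_c_pg)
        replicate_values = []
        low_confidence = False
        for rep in range(spec.replicates):
            seed = (config.rng_seed + 10_000 * s_idx + rep) % 2**31
            acq = dataclasses.replace(
                config.acquisition, rng_seed=seed, scale="linear"
            )
            # genome sizing gates the G1 peaks only, so the mixed run is
            # acquired with all sample nuclei at 2C
            g1_truth = SpeciesTruth(spec.name, spec.two_c_pg, {"2C": 1.0})
            events = simulate_mixed_run(g1_truth, std_truth, acq)
            sample_peak, standard_peak, std = _gate_mixed_run(
                events, spec, events.metadata["anchor"]
            )
            for peak in (sample_peak, standard_peak):
                if not qc_cv(peak, config.max_cv_percent):
                    low_confidence = True
                    qc_log.append(
                        {
                            "species": spec.name,
                            "replicate": rep,
                            "peak": peak.label,
                            "cv_percent": round(peak.cv_percent, 2),
                            "max_cv_percent": config.max_cv_percent,
                            "event": "cv_qc_failed",
                        }
                    )
            replicate_values.append(
                estimate_two_c(
                    sample_peak.mean_position, standard_peak.mean_position, std
                )
            )
        est = summarize_replicates(replicate_values)
        est.low_confidence = low_confidence
        complete_estimate(est, spec.ploidy_multiplier)
        gs_rows.append(
            {
                "species": spec.name,
                "accession": spec.accession,
                "ploidy_multiplier": spec.ploidy_multiplier,
                "standard": spec.standard,
                "two_c_pg": round_half_up(est.two_c_pg_mean, 2),
                "two_c_se": round_half_up(est.two_c_pg_se, 2),
                "one_cx_pg": round_half_up(est.one_cx_pg, 2),
                "one_cx_mbp": est.one_cx_mbp,
                "qc_low_confidence": low_confidence,
            }
        )

        # endopolyploidy acquisition: no standard, log display
        seed = (config.rng_seed + 10_000 * s_idx + 9_999) % 2**31
        acq = dataclasses.replace(
            config.acquisition, rng_seed=seed, scale="logarithmic"
        )
        endo_events = simulate_nuclei_events(truth, acq)
        hist = build_histogram(endo_events, "logarithmic", 250)
        positions = detect_peaks(hist)
        if not positions:
            raise RuntimeError(f"{spec.name}: no endopolyploidy peaks found")
        base_peak = gate_peak(endo_events, positions[0], label="2C")
        profile = profile_from_events(
            endo_events,
            base_peak.mean_position,
            config.level_tolerance,
            taxon=spec.name,
            accession=spec.accession,
        )
        row = {
            "taxon": spec.name,
            "accession": spec.accession,
        }
        for lv, pct in profile.percent_per_level.items():
            row[f"pct_{lv.lower()}"] = round_half_up(pct, 2)
        row["n_endocycles"] = profile.n_endocycles
        row["cycle_value"] = profile.cycle_value
        row["polysomatic"] = profile.polysomatic
        endo_rows.append(row)

    gs_table = pd.DataFrame(gs_rows)
    endo_table = pd.DataFrame(endo_rows)

    stats_report = {}
    if config.run_statistics and len(config.species) >= 3:
        m = gs_table["ploidy_multiplier"].to_numpy(dtype=float)
        cx = gs_table["one_cx_pg"].to_numpy(dtype=float)
        if np.ptp(m) > 0 and np.ptp(cx) > 0:
            corr = pearson_with_regression(m, cx)
            stats_report["ploidy_vs_one_cx"] = {
                "r": round(corr.r, 4),
                "p_value": corr.p_value,
                "slope": corr.slope,
                "intercept": corr.intercept,
                "n": corr.n,
            }

    gs_table.to_csv(outdir / "genome_size.csv", index=False)
    endo_table.to_csv(outdir / "endopolyploidy.csv", index=False)
    with open(outdir / "statistics.json", "w") as fh:
        json.dump(stats_report, fh, indent=2, sort_keys=True)
    with open(outdir / "qc_log.json", "w") as fh:
        json.dump(qc_log, fh, indent=2)

    return {
        "genome_size": gs_table,
        "endopolyploidy": endo_table,
        "statistics": stats_report,
        "qc_log": qc_log,
    }


# ---------------------------------------------------------------------------
# survey-table statistics (works off the packaged or a user karyology CSV)


def karyology_statistics(table: Optional[pd.DataFrame] = None) -> dict:
    """Correlation and series-comparison layer over a karyology table.

    Expects the column layout of :func:`ploidyflow.datasets.load_karyology`.
    Populations are the analysis units.  Series with fewer than two
    populations are excluded from the ANOVA/Tukey stage, and chromosome
    counts are passed through the fixed-constant normalising transform
    first.
    """
    if table is None:
        table = datasets.load_karyology()
    m = table["multiplier"].to_numpy(dtype=float)
    two_n = table["two_n"].to_numpy(dtype=float)
    one_cx = (table["two_c_pg"] / table["multiplier"]).to_numpy(dtype=float)

    corr_2n = pearson_with_regression(m, two_n)
    corr_cx = pearson_with_regression(m, one_cx)

    counts = table.groupby("series")["two_n"].count()
    eligible = counts[counts >= 2].index
    sub = table[table["series"].isin(eligible)]
    groups = {
        name: boxcox_chromosome_transform(g["two_n"].to_numpy(dtype=float))
        for name, g in sub.groupby("series")
    }
    anova = one_way_anova(groups)
    tukey = tukey_kramer(groups)  # same transformed scale as the ANOVA
    means = series_group_means(sub)
    return {
        "ploidy_vs_2n": corr_2n,
        "ploidy_vs_one_cx": corr_cx,
        "series_anova": anova,
        "series_tukey": tukey,
        "series_mean_2n": means,
    }
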