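"""Stage orchestration: X-scan -> motif -> pattern -> scan -> filter,
plus the independent fitting and quantitation stages.

Each stage reads only its declared inputs and writes TSV/JSON outputs
into the configured output directory; a run manifest records the config
snapshot, input checksums, package version, timestamps, and per-stage
row counts. Stage outputs are deterministic for identical config and
inputs (the manifest's timestamps are the only non-reproducible bytes).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, required_inputs, validate_config
from .errors import ConfigError, TcrspecError
from .fit import DoseResponseSeries, KillCurve, fit_4pl, fit_kt50
from .normalize import AnchorMode, condition_values, normalize_table, read_readouts
from .peptide import Peptide
from .proteome import (
    builtin_anchor_scorer,
    compile_pattern,
    filter_by_affinity,
    parse_pattern,
    proteome_checksum,
    read_predictions,
    read_proteome,
    scan_proteome,
)
from .quant import copies_per_cell, read_prm_table
from .xscan import ActivityMatrix, RecognitionMotif, assemble_matrix, build_xscan_library, extract_motif

log = logging.getLogger("tcrspec")


@dataclass
class RunManifest:
    config: dict
    package_version: str
    input_checksums: dict = field(default_factory=dict)
    stage_rows: dict = field(default_factory=dict)
    stage_outputs: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    status: str = "incomplete"
    failed_stage: str | None = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig | dict | str) -> RunManifest:
    """Execute the selected stages in dependency order.

    Inputs for all selected stages are checked before any computation;
    a failing stage aborts the run, and the manifest names it.
    """
    config = validate_config(config)
    inputs = required_inputs(config)  # raises ConfigError before any work
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        config=config.to_dict(),
        package_version=__version__,
        started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    for key, path in inputs:
        manifest.input_checksums[key] = _sha256(path)

    state: dict = {}
    order = [s for s in ("xscan", "motif", "scan", "filter", "fit", "quant", "kt50") if s in config.stages]
    try:
        for stage in order:
            log.info("running stage %s", stage)
            rows, outputs = _STAGE_FUNCS[stage](config, state, outdir)
            manifest.stage_rows[stage] = rows
            manifest.stage_outputs[stage] = outputs
    except TcrspecError as exc:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        manifest.write(outdir / "manifest.json")
        raise ConfigError([f"stage {stage!r} failed: {exc}"]) from exc
    manifest.status = "ok"
    manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest.write(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_xscan(config: PipelineConfig, state: dict, outdir: Path):
    cognate = Peptide(config.cognate)
    df = read_readouts(config.xscan_readouts)
    normalized = normalize_table(df, anchor_mode=AnchorMode(config.anchor_mode))
    values = condition_values(normalized)
    library = build_xscan_library(cognate)
    matrix = assemble_matrix(library, values)
    state["matrix"] = matrix
    norm_path, mat_path = outdir / "normalized.tsv", outdir / "activity_matrix.tsv"
    _write_tsv(normalized, norm_path)
    matrix.to_tsv(mat_path)
    return len(normalized), [norm_path.name, mat_path.name]


def _stage_motif(config: PipelineConfig, state: dict, outdir: Path):
    matrix = state.get("matrix")
    if matrix is None:
        matrix = ActivityMatrix.from_tsv(config.activity_matrix, Peptide(config.cognate))
    motif = extract_motif(matrix, threshold=config.motif_threshold)
    pattern = compile_pattern(motif)
    state["motif"], state["pattern"] = motif, pattern
    motif_path, pattern_path = outdir / "motif.json", outdir / "pattern.txt"
    with open(motif_path, "w") as fh:
        json.dump(motif.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    pattern_path.write_text(pattern.pattern_text + "\n")
    return len(motif), [motif_path.name, pattern_path.name]


def _stage_scan(config: PipelineConfig, state: dict, outdir: Path):
    pattern = state.get("pattern")
    if pattern is None:
        pattern = parse_pattern(Path(config.pattern_file).read_text().strip())
    records = read_proteome(config.proteome)
    matches = scan_proteome(pattern, records, cognate=config.cognate)
    state["matches"] = matches
    df = pd.DataFrame(
        [
            {
                "protein_id": m.protein_id,
                "start": m.start,
                "end": m.end,
                "matched_sequence": m.matched_sequence,
                "is_cognate": m.is_cognate,
            }
            for m in matches
        ],
        columns=["protein_id", "start", "end", "matched_sequence", "is_cognate"],
    )
    path = outdir / "matches.tsv"
    _write_tsv(df, path)
    (outdir / "proteome.sha256").write_text(proteome_checksum(config.proteome) + "\n")
    return len(df), [path.name, "proteome.sha256"]


def _stage_filter(config: PipelineConfig, state: dict, outdir: Path):
    matches = state.get("matches")
    if matches is None:
        raise ConfigError(["filter stage requires the scan stage in the same run"])
    if config.predictor == "external":
        predictions = read_predictions(config.predictions)
    else:
        predictions = [
            builtin_anchor_scorer(seq, config.allele)
            for seq in sorted({m.matched_sequence for m in matches if not m.is_cognate})
        ]
    cand = filter_by_affinity(
        matches, predictions, allele=config.allele, threshold_nm=config.affinity_threshold_nm
    )
    rows = []
    for m, p in cand.candidates:
        rows.append(
            {
                "protein_id": m.protein_id,
                "start": m.start,
                "matched_sequence": m.matched_sequence,
                "predicted_ec50_nm": p.predicted_ec50,
                "predictor_id": p.predictor_id,
                "status": "candidate",
            }
        )
    for ex in cand.excluded:
        rows.append(
            {
                "protein_id": ex.match.protein_id,
                "start": ex.match.start,
                "matched_sequence": ex.match.matched_sequence,
                "predicted_ec50_nm": ex.prediction.predicted_ec50,
                "predictor_id": ex.prediction.predictor_id,
                "status": f"excluded:{ex.reason}",
            }
        )
    for m in cand.cognate_matches:
        rows.append(
            {
                "protein_id": m.protein_id,
                "start": m.start,
                "matched_sequence": m.matched_sequence,
                "predicted_ec50_nm": float("nan"),
                "predictor_id": "",
                "status": "cognate",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["protein_id", "start", "matched_sequence", "predicted_ec50_nm", "predictor_id", "status"],
    ).sort_values(["protein_id", "start"], kind="stable")
    path = outdir / "candidates.tsv"
    _write_tsv(df, path)
    return len(df), [path.name]


def _stage_fit(config: PipelineConfig, state: dict, outdir: Path):
    df = pd.read_csv(config.dose_response, sep="\t")
    if "series_id" not in df.columns:
        df["series_id"] = "series1"
    rows = []
    for sid, grp in df.groupby("series_id", sort=True):
        series = DoseResponseSeries(
            concentrations=grp["concentration_M"].to_numpy(),
            responses=grp["response"].to_numpy(),
            label=str(sid),
        )
        fit = fit_4pl(series)
        rows.append(
            {
                "series_id": sid,
                "ec50_M": fit.ec50,
                "hill": fit.hill,
                "top": fit.top,
                "bottom": fit.bottom,
                "converged": fit.converged,
                "extrapolated": fit.extrapolated,
                "rss": fit.rss,
            }
        )
    out = pd.DataFrame(rows)
    path = outdir / "dose_response_fits.tsv"
    _write_tsv(out, path)
    return len(out), [path.name]


def _stage_quant(config: PipelineConfig, state: dict, outdir: Path):
    samples = read_prm_table(config.prm_table)
    rows = []
    for sample in samples:
        res = copies_per_cell(sample)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "peptide": sample.peptide.sequence if sample.peptide else "",
                "allele": sample.allele,
                "copies_per_cell": res.copies_per_cell,
                "moles_eluted_total": res.moles_eluted_total,
                "abundance_class": res.abundance_class.value,
                "n_injections": len(sample.injections),
            }
        )
    out = pd.DataFrame(rows)
    path = outdir / "copies_per_cell.tsv"
    _write_tsv(out, path)
    return len(out), [path.name]


def _stage_kt50(config: PipelineConfig, state: dict, outdir: Path):
    df = pd.read_csv(config.killcurves, sep="\t")
    if "curve_id" not in df.columns:
        df["curve_id"] = "curve1"
    rows = []
    for cid, grp in df.groupby("curve_id", sort=True):
        curve = KillCurve(
            times=grp["time_h"].to_numpy(), index=grp["index"].to_numpy(), label=str(cid)
        )
        res = fit_kt50(curve)
        rows.append(
            {
                "curve_id": cid,
                "kt50_h": res.kt50 if res.kt50 is not None else float("nan"),
                "censored": res.censored,
                "label": res.label,
                "rate_per_h": res.rate,
                "outgrowth": res.outgrowth,
            }
        )
    out = pd.DataFrame(rows)
    path = outdir / "kt50.tsv"
    _write_tsv(out, path)
    return len(out), [path.name]


_STAGE_FUNCS = {
    "xscan": _stage_xscan,
    "motif": _stage_motif,
    "scan": _stage_scan,
    "filter": _stage_filter,
    "fit": _stage_fit,
    "quant": _stage_quant,
    "kt50": _stage_kt50,
}
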