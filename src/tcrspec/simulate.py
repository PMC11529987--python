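"""Synthetic-data generators with recorded ground truth.

Every pipeline input can be generated here with its ground truth
serialized beside it, so each analysis stage is testable without any
external download. All generators are deterministic under a fixed seed;
each derives its own substream by hashing a generator id into the seed
sequence, so adding a generator never perturbs the draws of another.

The defaults emulate the reference study conditions: dose-response
series over a 10 uM - 1 pM titration with ~5-point Gaussian readout
noise, X-scan readouts whose tolerated/rejected activity ranges
straddle the 50% motif cutoff, PRM injections in duplicate with a
200 fmol heavy spike and half the sample per injection, and 72-hour
kill curves sampled hourly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .fit import DoseResponseSeries, KillCurve
from .peptide import AMINO_ACIDS, Peptide
from .proteome import DegeneratePattern
from .quant import AVOGADRO, Injection, PRMSample
from .xscan import RecognitionMotif, build_xscan_library, condition_id

__all__ = [
    "SyntheticTruth",
    "substream",
    "default_concentration_grid",
    "gen_dose_response",
    "gen_xscan",
    "gen_proteome",
    "gen_prm",
    "gen_killcurve",
    "write_fasta",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth sidecar for a generated dataset."""

    seed: int
    generator_id: str
    parameters: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(seed=d["seed"], generator_id=d["generator_id"], parameters=d["parameters"])


def substream(seed: int, generator_id: str) -> np.random.Generator:
    """Independent RNG substream: seed plus a stable hash of the generator id."""
    h = int.from_bytes(hashlib.sha256(generator_id.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


def default_concentration_grid() -> np.ndarray:
    """Half-log10-spaced titration from 10 uM down to 1 pM (15 points)."""
    return 10.0 ** np.arange(-5.0, -12.1, -0.5)


def gen_dose_response(
    ec50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    concentrations: Sequence[float] | None = None,
    noise_sd: float = 5.0,
    seed: int = 0,
    label: str = "",
) -> tuple[DoseResponseSeries, SyntheticTruth]:
    """Noisy 4PL responses on a titration grid, clipped to [0, 100]."""
    conc = (
        default_concentration_grid()
        if concentrations is None
        else np.asarray(concentrations, dtype=float)
    )
    rng = substream(seed, f"dose_response:{label}")
    ideal = bottom + (top - bottom) / (1.0 + (ec50 / conc) ** hill)
    resp = ideal + (rng.normal(0.0, noise_sd, size=conc.shape) if noise_sd > 0 else 0.0)
    resp = np.clip(resp, 0.0, 100.0)
    truth = SyntheticTruth(
        seed=seed,
        generator_id="gen_dose_response",
        parameters={
            "ec50": ec50,
            "hill": hill,
            "top": top,
            "bottom": bottom,
            "noise_sd": noise_sd,
            "label": label,
            "concentrations": list(map(float, conc)),
        },
    )
    return DoseResponseSeries(concentrations=conc, responses=resp, label=label), truth


def gen_xscan(
    latent_motif: RecognitionMotif,
    seed: int = 0,
    tolerated_range: tuple[float, float] = (60.0, 100.0),
    rejected_range: tuple[float, float] = (0.0, 40.0),
) -> tuple[dict[str, float], SyntheticTruth]:
    """X-scan readouts drawn from a latent per-position tolerance motif.

    Tolerated residues draw uniform activities from ``tolerated_range``,
    others from ``rejected_range``; cognate cells are 100 exactly. With
    the default ranges straddling the 50% cutoff, motif extraction
    recovers the latent motif exactly; overlapping ranges void that
    guarantee (recovery is then probabilistic, by design).
    """
    rng = substream(seed, "xscan")
    library = build_xscan_library(latent_motif.cognate)
    readouts: dict[str, float] = {}
    for entry in library.entries:
        lo, hi = (
            tolerated_range
            if entry.residue in latent_motif.sets[entry.position - 1]
            else rejected_range
        )
        readouts[entry.condition_id] = float(rng.uniform(lo, hi))
    for pos in range(1, len(latent_motif.cognate) + 1):
        readouts[condition_id(pos, latent_motif.cognate[pos - 1])] = 100.0
    truth = SyntheticTruth(
        seed=seed,
        generator_id="gen_xscan",
        parameters={
            "cognate": latent_motif.cognate.sequence,
            "threshold": latent_motif.threshold,
            "latent_sets": ["".join(sorted(s)) for s in latent_motif.sets],
            "tolerated_range": list(tolerated_range),
            "rejected_range": list(rejected_range),
        },
    )
    return readouts, truth


def gen_proteome(
    n_proteins: int = 1000,
    mean_length: int = 350,
    pattern: DegeneratePattern | None = None,
    n_planted: int = 0,
    seed: int = 0,
    background_freqs: Mapping[str, float] | None = None,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Random proteome with optional planted degenerate-pattern instances.

    Residues are i.i.d. from a background table (uniform 1/20 by
    default, keeping incidental-match expectations closed-form). Each
    planted instance is a random realization of the pattern written at a
    recorded (protein, start) position; plant sites never overlap one
    another, though incidental matches elsewhere can and do occur.
    """
    if n_planted > 0 and pattern is None:
        raise ValidationError("cannot plant matches without a pattern")
    rng = substream(seed, "proteome")
    aas = np.array(list(AMINO_ACIDS))
    if background_freqs is None:
        probs = np.full(20, 1.0 / 20.0)
    else:
        probs = np.array([background_freqs.get(a, 0.0) for a in AMINO_ACIDS])
        if not np.isclose(probs.sum(), 1.0):
            raise ValidationError("background frequencies must sum to 1")
    min_len = len(pattern) if pattern is not None else 1
    lengths = np.maximum(rng.poisson(mean_length, size=n_proteins), min_len)
    width = len(str(n_proteins))
    records = [
        (f"SYN{i:0{width}d}", "".join(rng.choice(aas, size=int(L), p=probs)))
        for i, L in enumerate(lengths, start=1)
    ]

    planted: list[dict] = []
    if n_planted:
        occupied: dict[int, list[tuple[int, int]]] = {}
        n = len(pattern)
        attempts = 0
        while len(planted) < n_planted:
            attempts += 1
            if attempts > 1000 * n_planted:
                raise ValidationError("could not place all planted matches")
            idx = int(rng.integers(0, n_proteins))
            rid, seq = records[idx]
            if len(seq) < n:
                continue
            start0 = int(rng.integers(0, len(seq) - n + 1))
            span = (start0, start0 + n)
            if any(s < span[1] and span[0] < e for s, e in occupied.get(idx, [])):
                continue
            realization = "".join(
                sorted(s)[int(rng.integers(0, len(s)))] for s in pattern.per_position_sets
            )
            records[idx] = (rid, seq[:start0] + realization + seq[span[1] :])
            occupied.setdefault(idx, []).append(span)
            planted.append(
                {"protein_id": rid, "start": start0 + 1, "sequence": realization}
            )
        planted.sort(key=lambda p: (p["protein_id"], p["start"]))

    truth = SyntheticTruth(
        seed=seed,
        generator_id="gen_proteome",
        parameters={
            "n_proteins": n_proteins,
            "mean_length": mean_length,
            "pattern": pattern.pattern_text if pattern is not None else None,
            "n_planted": n_planted,
            "planted": planted,
            "background": "uniform" if background_freqs is None else dict(background_freqs),
        },
    )
    return records, truth


def write_fasta(records: Sequence[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def gen_prm(
    true_copies_per_cell: float,
    input_cells: float = 1e8,
    spike: float = 200e-15,
    fraction: float = 0.5,
    noise_cv: float = 0.0,
    n_injections: int = 2,
    seed: int = 0,
    peptide: str = "VVVGAVGVGK",
    allele: str = "A*11:01",
    sample_id: str = "synthetic",
) -> tuple[PRMSample, SyntheticTruth]:
    """PRM peak areas implied by a known copies/cell ground truth.

    The noiseless light/heavy ratio is
    ``true_copies x cells x fraction / (spike x N_A)``; multiplicative
    lognormal noise with the given CV (median 1, so recovery is
    median-unbiased) perturbs each injection independently.
    """
    if true_copies_per_cell < 0:
        raise ValidationError("true copies/cell must be >= 0")
    rng = substream(seed, f"prm:{sample_id}")
    ratio = true_copies_per_cell * input_cells * fraction / (spike * AVOGADRO)
    heavy = 1.0e6  # arbitrary instrument units; only the ratio matters
    injections = []
    for _ in range(n_injections):
        noise = float(np.exp(rng.normal(0.0, noise_cv))) if noise_cv > 0 else 1.0
        injections.append(Injection(light_area=ratio * noise * heavy, heavy_area=heavy))
    sample = PRMSample(
        sample_id=sample_id,
        injections=tuple(injections),
        spike_amount=spike,
        injected_fraction=fraction,
        input_cells=input_cells,
        peptide=Peptide(peptide),
        allele=allele,
    )
    truth = SyntheticTruth(
        seed=seed,
        generator_id="gen_prm",
        parameters={
            "true_copies_per_cell": true_copies_per_cell,
            "input_cells": input_cells,
            "spike_mol": spike,
            "fraction": fraction,
            "noise_cv": noise_cv,
            "n_injections": n_injections,
            "sample_id": sample_id,
        },
    )
    return sample, truth


def gen_killcurve(
    true_kt50: float,
    t_max: float = 72.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    effector_target_ratio: float = 3.0,
    label: str = "",
) -> tuple[KillCurve, SyntheticTruth]:
    """Exponential-decay kill curve sampled hourly, index(0) forced to 1."""
    if true_kt50 <= 0:
        raise ValidationError("true KT50 must be positive")
    rng = substream(seed, f"killcurve:{label}")
    times = np.arange(0.0, t_max + 0.5, 1.0)
    index = np.exp(-np.log(2.0) * times / true_kt50)
    if noise_sd > 0:
        index = index + rng.normal(0.0, noise_sd, size=times.shape)
    index = np.clip(index, 0.0, None)
    index[0] = 1.0
    curve = KillCurve(
        times=times,
        index=index,
        effector_target_ratio=effector_target_ratio,
        label=label,
    )
    truth = SyntheticTruth(
        seed=seed,
        generator_id="gen_killcurve",
        parameters={
            "true_kt50": true_kt50,
            "t_max": t_max,
            "noise_sd": noise_sd,
            "effector_target_ratio": effector_target_ratio,
            "label": label,
        },
    )
    return curve, truth


# ---------------------------------------------------------------------------
# Full synthetic input bundle for an end-to-end pipeline run
# ---------------------------------------------------------------------------


def default_latent_motif(cognate: Peptide, seed: int = 0) -> RecognitionMotif:
    """A plausible latent TCR recognition motif for simulation.

    Encodes the qualitative footprint seen for KRAS G12V TCRs: a fully
    tolerant P1, restricted N-terminal (P2) and C-terminal (K/R) anchor
    positions, a mutation position (P6 of the decamer, P5 of the
    nonamer) tolerating only the cognate valine, and a seeded random
    sprinkle of tolerated residues elsewhere.
    """
    rng = substream(seed, "latent_motif")
    n = len(cognate)
    mut_pos = 6 if n == 10 else 5
    sets = []
    for pos in range(1, n + 1):
        cog = cognate[pos - 1]
        if pos == 1:
            sets.append(frozenset(AMINO_ACIDS))
        elif pos == 2:
            sets.append(frozenset({cog, "I", "L"}))
        elif pos == mut_pos:
            sets.append(frozenset({cog}))
        elif pos == n:
            sets.append(frozenset({cog, "R"}))
        else:
            extra = rng.choice(list(AMINO_ACIDS), size=int(rng.integers(1, 4)), replace=False)
            sets.append(frozenset({cog, *extra}))
    return RecognitionMotif(cognate=cognate, sets=tuple(sets), threshold=50.0)


def write_bundle(outdir, seed: int = 0, cognate: str = "VVVGAVGVGK") -> dict:
    """Write every pipeline input (with truth sidecars) into ``outdir``.

    Returns a config dict wired to the generated files, suitable for
    :func:`tcrspec.pipeline.run_pipeline`. Also writes it as
    ``config.yaml``.
    """
    import pandas as pd
    import yaml

    from .proteome import compile_pattern

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cog = Peptide(cognate)

    # --- X-scan readouts (raw reporter %GFP, long format with anchors) ---
    motif = default_latent_motif(cog, seed=seed)
    readouts, xscan_truth = gen_xscan(motif, seed=seed)
    gfp_min, gfp_max = 2.0, 82.0
    rows = [
        {"condition_id": "no_peptide", "replicate_id": "r1", "raw_value": gfp_min, "role": "min"},
        {"condition_id": "cognate", "replicate_id": "r1", "raw_value": gfp_max, "role": "max"},
    ]
    for cond, value in sorted(readouts.items()):
        rows.append(
            {
                "condition_id": cond,
                "replicate_id": "r1",
                "raw_value": gfp_min + value / 100.0 * (gfp_max - gfp_min),
                "role": "test",
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "xscan_readouts.tsv", sep="\t", index=False)
    xscan_truth.to_json(outdir / "xscan_truth.json")

    # --- Proteome with planted motif matches ---
    pattern = compile_pattern(motif)
    records, prot_truth = gen_proteome(
        n_proteins=300, mean_length=350, pattern=pattern, n_planted=5, seed=seed
    )
    write_fasta(records, outdir / "proteome.fasta")
    prot_truth.to_json(outdir / "proteome_truth.json")

    # --- Dose-response series at study-anchored EC50s ---
    dr_rows, dr_truths = [], {}
    for label, ec50 in (("high_avidity", 2.6e-10), ("mid_avidity", 7.4e-9), ("low_avidity", 1.97e-7)):
        series, truth = gen_dose_response(ec50=ec50, noise_sd=5.0, seed=seed, label=label)
        dr_truths[label] = truth.parameters
        for c, r in zip(series.concentrations, series.responses):
            dr_rows.append({"series_id": label, "concentration_M": c, "response": r})
    pd.DataFrame(dr_rows).to_csv(outdir / "dose_response.tsv", sep="\t", index=False)
    SyntheticTruth(seed=seed, generator_id="gen_dose_response", parameters=dr_truths).to_json(
        outdir / "dose_response_truth.json"
    )

    # --- PRM peak areas at study-range copies/cell ---
    prm_rows, prm_truths = [], {}
    for sid, true_copies in (
        ("high_242", 242.2),
        ("intermediate_71", 71.2),
        ("low_34", 34.6),
        ("trace_1.6", 1.6),
    ):
        sample, truth = gen_prm(true_copies, noise_cv=0.05, seed=seed, sample_id=sid, peptide=cognate)
        prm_truths[sid] = truth.parameters
        for i, inj in enumerate(sample.injections, start=1):
            prm_rows.append(
                {
                    "sample_id": sid,
                    "peptide": cognate,
                    "allele": sample.allele,
                    "injection_id": f"inj{i}",
                    "light_area": inj.light_area,
                    "heavy_area": inj.heavy_area,
                    "spike_fmol": sample.spike_amount / 1e-15,
                    "injected_fraction": sample.injected_fraction,
                    "input_cells": sample.input_cells,
                }
            )
    pd.DataFrame(prm_rows).to_csv(outdir / "prm.tsv", sep="\t", index=False)
    SyntheticTruth(seed=seed, generator_id="gen_prm", parameters=prm_truths).to_json(
        outdir / "prm_truth.json"
    )

    # --- Kill curves ---
    kc_rows, kc_truths = [], {}
    for cid, kt50 in (("fast_24h", 24.0), ("slow_40h", 40.0), ("no_kill", 1000.0)):
        curve, truth = gen_killcurve(kt50, t_max=72.0, noise_sd=0.05, seed=seed, label=cid)
        kc_truths[cid] = truth.parameters
        for t, x in zip(curve.times, curve.index):
            kc_rows.append({"curve_id": cid, "time_h": t, "index": x})
    pd.DataFrame(kc_rows).to_csv(outdir / "killcurves.tsv", sep="\t", index=False)
    SyntheticTruth(seed=seed, generator_id="gen_killcurve", parameters=kc_truths).to_json(
        outdir / "killcurves_truth.json"
    )

    config = {
        "seed": seed,
        "cognate": cognate,
        "output_dir": str(outdir / "out"),
        "xscan_readouts": str(outdir / "xscan_readouts.tsv"),
        "proteome": str(outdir / "proteome.fasta"),
        "dose_response": str(outdir / "dose_response.tsv"),
        "prm_table": str(outdir / "prm.tsv"),
        "killcurves": str(outdir / "killcurves.tsv"),
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config
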