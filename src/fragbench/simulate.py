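"""Seedable synthetic data: ground-truth fragment profiles, noisy replicate
spectra, and simulated predictors of controlled accuracy.

The generative model is deliberately simple: true relative b/y intensity
profiles are drawn from a symmetric Dirichlet over the canonical fragment
layout and L2-normalized; experimental replicates multiply the truth by
lognormal noise of configurable CV, drop peaks independently, and jitter
m/z within (below) the matching tolerance; each simulated predictor applies
its own lognormal error to the truth.  Everything is deterministic given
the seed.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import Peptide, theoretical_mz_array
from .errors import ConfigError
from .io import (
    PrecursorRow,
    PredictionTable,
    PsmRecord,
    SpectrumRecord,
    write_mgf,
    write_precursor_table,
    write_predictions,
)
from .similarity import LAYOUT_CHARGE1, LAYOUT_CHARGE12, IntensityVector

RESIDUES = "".join(c for c in string.ascii_uppercase if c in
                   "GASPVTCLINDQKEMHFRYW")


@dataclass
class SynthConfig:
    n_precursors: int = 200
    length_range: tuple[int, int] = (7, 20)
    charge_probs: dict[int, float] = field(default_factory=lambda: {2: 0.6, 3: 0.4})
    replicate_count_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.3, 2: 0.4, 3: 0.3})
    dirichlet_alpha: float = 1.0
    replicate_noise_cv: float = 0.05
    dropout_prob: float = 0.02
    mz_jitter_ppm: float = 5.0
    predictor_noise_cvs: dict[str, float] = field(
        default_factory=lambda: {"methodA": 0.1, "methodB": 0.3})
    seed: int = 0
    tryptic: bool = True
    charges: tuple[int, ...] = (1, 2)
    nce: float = 27.0
    instrument: str = "QE"
    dissociation: str = "HCD"
    mass_analyzer: str = "FTMS"
    match_tol_ppm: float = 20.0
    n_decoy_peaks: int = 0

    def __post_init__(self):
        for name, probs in (("charge_probs", self.charge_probs),
                            ("replicate_count_dist", self.replicate_count_dist)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, got {sum(probs.values())}")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"{name} contains a negative probability")
        lo, hi = self.length_range
        if not 2 <= lo <= hi:
            raise ConfigError(f"invalid length range {self.length_range}")
        if not 0 <= self.dropout_prob < 1:
            raise ConfigError("dropout_prob must be in [0, 1)")
        if self.mz_jitter_ppm >= self.match_tol_ppm:
            raise ConfigError("mz_jitter_ppm must stay below the matching tolerance")
        for v in (self.replicate_noise_cv, self.mz_jitter_ppm, self.dirichlet_alpha):
            if v < 0:
                raise ConfigError("noise parameters must be non-negative")
        if any(cv < 0 for cv in self.predictor_noise_cvs.values()):
            raise ConfigError("predictor noise CVs must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("charge_probs", "replicate_count_dist"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        if "predictor_noise_cvs" in d:
            d["predictor_noise_cvs"] = {str(k): float(v)
                                        for k, v in d["predictor_noise_cvs"].items()}
        if "length_range" in d:
            d["length_range"] = tuple(d["length_range"])
        if "charges" in d:
            d["charges"] = tuple(d["charges"])
        return cls(**d)


@dataclass
class SimPrecursor:
    peptide: Peptide
    charge: int
    meta: PrecursorRow
    true_vector: IntensityVector
    replicate_count: int


@dataclass
class GroundTruth:
    config: SynthConfig
    precursors: list[SimPrecursor]


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _draw_from(rng: np.random.Generator, probs: dict) -> object:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys])
    return keys[rng.choice(len(keys), p=p / p.sum())]


def generate_truth(config: SynthConfig) -> GroundTruth:
    """Draw precursors, acquisition metadata and unit-norm true profiles."""
    rng = np.random.default_rng([config.seed, 0])
    layout = LAYOUT_CHARGE1 if tuple(config.charges) == (1,) else LAYOUT_CHARGE12
    seen: set[tuple[str, int]] = set()
    precursors: list[SimPrecursor] = []
    lo, hi = config.length_range
    while len(precursors) < config.n_precursors:
        n = int(rng.integers(lo, hi + 1))
        letters = [RESIDUES[i] for i in rng.integers(0, len(RESIDUES), size=n)]
        if config.tryptic:
            letters[-1] = "K" if rng.random() < 0.5 else "R"
        sequence = "".join(letters)
        charge = int(_draw_from(rng, config.charge_probs))
        # carbamidomethyl as a fixed mod on every C, matching the parser
        mods = tuple((i, "Carbamidomethyl")
                     for i, aa in enumerate(sequence, start=1) if aa == "C")
        peptide = Peptide(sequence, mods)
        pid = (peptide.proforma(), charge)
        if pid in seen:
            continue
        # reject precursors with (near-)degenerate theoretical m/z, e.g.
        # b2^2+ of WW... equals b1^+ exactly; such peaks are inseparable by
        # any matcher and would make identity tests uninterpretable
        theo = np.sort(theoretical_mz_array(peptide, config.charges))
        if np.diff(theo).min() < 1e-4:
            continue
        seen.add(pid)
        dim = len(config.charges) * 2 * (n - 1)
        profile = rng.dirichlet(np.full(dim, config.dirichlet_alpha))
        profile = profile / np.linalg.norm(profile)
        meta = PrecursorRow(peptide, charge, config.nce, config.instrument,
                            config.dissociation, config.mass_analyzer)
        reps = int(_draw_from(rng, config.replicate_count_dist))
        precursors.append(SimPrecursor(peptide, charge, meta,
                                       IntensityVector(profile, layout), reps))
    return GroundTruth(config, precursors)


def emit_experimental(
    truth: GroundTruth,
) -> tuple[list[SpectrumRecord], list[PsmRecord]]:
    """Noisy replicate spectra plus the PSM table linking them to precursors.

    Each replicate multiplies the true profile by lognormal noise, drops
    peaks independently, jitters m/z uniformly within the configured ppm
    bound, and is written with a fresh scan number into one source file.
    """
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, 1])
    source = "synthetic.raw"
    spectra: list[SpectrumRecord] = []
    psms: list[PsmRecord] = []
    scan = 0
    for prec in truth.precursors:
        theo = theoretical_mz_array(prec.peptide, cfg.charges)
        for _ in range(prec.replicate_count):
            scan += 1
            intens = prec.true_vector.values * _lognormal_factors(
                rng, cfg.replicate_noise_cv, len(theo))
            if cfg.dropout_prob > 0:
                intens = np.where(rng.random(len(theo)) < cfg.dropout_prob, 0.0, intens)
            jitter = rng.uniform(-cfg.mz_jitter_ppm, cfg.mz_jitter_ppm, len(theo)) * 1e-6
            mz = theo * (1.0 + jitter)
            keep = intens > 0
            mz, intens = mz[keep], intens[keep]
            if cfg.n_decoy_peaks:
                decoy_mz = rng.uniform(theo.min() * 0.5, theo.max() * 1.2,
                                       cfg.n_decoy_peaks)
                # keep decoys away from every theoretical fragment so they
                # can never be matched
                guard = theo * 3 * cfg.match_tol_ppm * 1e-6
                ok = np.abs(decoy_mz[:, None] - theo[None, :]).min(axis=1) > guard.max()
                decoy_mz = decoy_mz[ok]
                mz = np.concatenate([mz, decoy_mz])
                intens = np.concatenate(
                    [intens, rng.uniform(0.001, 0.01, len(decoy_mz))])
            spectra.append(SpectrumRecord(source, scan, mz, intens))
            psms.append(PsmRecord(source, scan, prec.peptide, prec.charge))
    return spectra, psms


def emit_predictions(truth: GroundTruth) -> dict[str, PredictionTable]:
    """One prediction table per simulated method; error grows with its CV."""
    cfg = truth.config
    layout = LAYOUT_CHARGE1 if tuple(cfg.charges) == (1,) else LAYOUT_CHARGE12
    tables: dict[str, PredictionTable] = {}
    for m, method in enumerate(sorted(cfg.predictor_noise_cvs)):
        cv = cfg.predictor_noise_cvs[method]
        rng = np.random.default_rng([cfg.seed, 2, m])
        table = PredictionTable(method)
        for prec in truth.precursors:
            vec = prec.true_vector.values * _lognormal_factors(rng, cv,
                                                               len(prec.true_vector))
            norm = np.linalg.norm(vec)
            if norm > 0:
                vec = vec / norm
            table.entries[(prec.peptide.proforma(), prec.charge)] = IntensityVector(
                vec, layout)
        tables[method] = table
    return tables


def write_bundle(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Write spectra.mgf, psms.tsv, precursors.tsv, predictions_*.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    spectra, psms = emit_experimental(truth)
    paths = {"mgf": outdir / "spectra.mgf", "psms": outdir / "psms.tsv",
             "precursors": outdir / "precursors.tsv", "truth": outdir / "truth.json"}
    write_mgf(spectra, paths["mgf"])
    with open(paths["psms"], "w", encoding="utf-8") as fh:
        fh.write("raw_file\tscan\tsequence\tmodifications\tcharge\n")
        for psm in psms:
            mods = ";".join(f"{pos}:{name}" for pos, name in psm.peptide.mods)
            fh.write(f"{psm.source_file}\t{psm.scan}\t{psm.peptide.sequence}"
                     f"\t{mods}\t{psm.charge}\n")
    write_precursor_table((p.meta for p in truth.precursors), paths["precursors"])
    for method, table in emit_predictions(truth).items():
        p = outdir / f"predictions_{method}.tsv"
        write_predictions(table, p, cfg.charges)
        paths[f"predictions_{method}"] = p
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump({
            "seed": cfg.seed,
            "n_precursors": cfg.n_precursors,
            "predictor_noise_cvs": cfg.predictor_noise_cvs,
            "replicate_noise_cv": cfg.replicate_noise_cv,
            "precursors": [
                {"sequence": p.peptide.proforma(), "charge": p.charge,
                 "replicates": p.replicate_count,
                 "true_profile": [round(v, 10) for v in p.true_vector.values]}
                for p in truth.precursors
            ],
        }, fh, indent=1)
        fh.write("\n")
    return paths
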