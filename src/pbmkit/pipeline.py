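"""End-to-end two-allele specificity comparison.

simulate (or load) duplicate PBM experiments for a reference and a variant
protein -> 8-mer E-score tables -> Seed-and-Wobble primary and secondary
motifs -> cross-allele pattern E-scores and motif comparisons -> optional
EMSA Kd fits and affinity ratios -> TSV/MEME outputs plus a machine-
readable JSON summary with a content-hash manifest. The whole run is a
pure function of the configuration (seeds included): re-running with the
same config produces bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .design import design_array
from .emsa import affinity_ratio, fit_kd
from .kmer import UndefinedScoreError, all_escores, pattern_escore
from .motif import SeedAndWobble, compare_pwms
from .simulate import consensus_pwm, simulate_two_allele

__all__ = ["RunConfig", "run_allele_comparison", "validate_config"]

DEFAULT_PATTERNS = (
    "GGGTATCA",     # reference-allele primary consensus
    "GGGTATCW",     # degenerate reference primary
    "TGTGTCAT",     # variant-allele (GTGT-core) consensus
    "NGTGTNNN",     # GTGT core with wildcard flanks
    "GGKGTCAT",     # degenerate variant
    "TAATTGNN",     # unrelated control pattern
)


@dataclass
class AlleleConfig:
    label: str
    consensus: str
    dominance: float = 0.85


@dataclass
class RunConfig:
    """Declarative configuration of a full two-allele run."""

    # array design
    coverage_k: int = 10
    probe_length: int = 36
    design_seed: int = 0
    # ground truth per allele
    reference: AlleleConfig = field(
        default_factory=lambda: AlleleConfig("SIX1-ref", "GGGTATCA"))
    variant: AlleleConfig = field(
        default_factory=lambda: AlleleConfig("SIX1-Q177R", "TGTGTCAT"))
    background: float = 200.0
    scale: float = 50000.0
    noise_sigma: float = 0.2
    sim_seed: int = 0
    n_replicates: int = 2
    # scoring
    escore_k: int = 8
    min_foreground: int = 20
    # wobble
    flank: int = 3
    pseudo: float = 1e-3
    # reporting
    patterns: tuple[str, ...] = DEFAULT_PATTERNS
    emsa_inputs: dict[str, str] = field(default_factory=dict)
    outdir: str = "pbmkit_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key in ("reference", "variant"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = AlleleConfig(**kwargs[key])
        if "patterns" in kwargs:
            kwargs["patterns"] = tuple(kwargs["patterns"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def validate_config(config: RunConfig) -> list[str]:
    """All violations found in the config (empty list when valid)."""
    errs = []
    if not 1 <= config.coverage_k <= 12:
        errs.append(f"coverage_k {config.coverage_k} outside [1, 12]")
    if not config.coverage_k < config.probe_length <= 100:
        errs.append(f"probe_length {config.probe_length} must be in (coverage_k, 100]")
    if not 1 <= config.escore_k <= 10:
        errs.append(f"escore_k {config.escore_k} outside [1, 10]")
    if config.escore_k + 2 * config.flank > config.probe_length:
        errs.append("flank too large for probe length")
    if config.noise_sigma < 0:
        errs.append("noise_sigma must be >= 0")
    if config.background <= 0 or config.scale < 0:
        errs.append("background must be > 0 and scale >= 0")
    if config.n_replicates < 1:
        errs.append("n_replicates must be >= 1")
    for allele in (config.reference, config.variant):
        if set(allele.consensus) - set("ACGT"):
            errs.append(f"allele {allele.label}: consensus must be over ACGT")
        if not 0.25 <= allele.dominance <= 1.0:
            errs.append(f"allele {allele.label}: dominance outside [0.25, 1]")
    for label, path in config.emsa_inputs.items():
        if not Path(path).exists():
            errs.append(f"EMSA input for {label!r} not found: {path}")
    return errs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_allele_comparison(config: RunConfig) -> dict:
    """Run the full comparison; returns the JSON-serialisable report.

    Writes per experiment: probe table, E-score TSV, MEME motif file and IC
    tables; plus a cross-allele pattern E-score table, motif comparisons,
    optional EMSA fits, a run log, and report.json with a file manifest.
    Partial outputs are removed if the run fails.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    try:
        from . import __version__
        log(f"pbmkit version {__version__}")
        log(f"design: k={config.coverage_k} probe_length={config.probe_length} "
            f"seed={config.design_seed}")
        design = design_array(config.coverage_k, config.probe_length,
                              config.design_seed)
        log(f"designed {len(design)} probes")

        pwm_ref = consensus_pwm(config.reference.consensus, config.reference.dominance)
        pwm_var = consensus_pwm(config.variant.consensus, config.variant.dominance)
        log(f"simulation: sigma={config.noise_sigma} seed={config.sim_seed} "
            f"replicates={config.n_replicates}")
        experiments = simulate_two_allele(
            design, pwm_ref, pwm_var,
            background=config.background, scale=config.scale,
            noise_sigma=config.noise_sigma, rng_seed=config.sim_seed,
            n_replicates=config.n_replicates,
            labels=(config.reference.label, config.variant.label),
        )

        report: dict = {"config": _config_dict(config), "experiments": []}
        fits_by_exp = []
        for exp in experiments:
            tag = f"{exp.protein_label}_rep{exp.replicate_id}"
            log(f"scoring {tag}")
            ppath = outdir / f"{tag}.probes.tsv"
            pio.write_probe_table(exp, ppath)
            written.append(ppath)

            table = all_escores(exp, k=config.escore_k,
                                min_foreground=config.min_foreground)
            epath = outdir / f"{tag}.escores.tsv"
            pio.write_escore_table(
                table, epath,
                meta={"protein_label": exp.protein_label,
                      "replicate_id": exp.replicate_id})
            written.append(epath)

            fit = SeedAndWobble(
                exp, k=config.escore_k, flank=config.flank,
                min_foreground=config.min_foreground, pseudo=config.pseudo,
            ).fit(escore_table=table)
            mpath = outdir / f"{tag}.motifs.meme"
            pio.write_meme({f"{tag}.{n}": p for n, p in fit.motifs().items()}, mpath)
            written.append(mpath)
            for name, pwm in fit.motifs().items():
                icp = outdir / f"{tag}.{name}.ic.tsv"
                pio.write_ic_table(pwm, icp)
                written.append(icp)

            pattern_scores = {}
            for pat in config.patterns:
                try:
                    pattern_scores[pat] = pattern_escore(exp, pat)
                except UndefinedScoreError:
                    pattern_scores[pat] = None
            fits_by_exp.append(fit)
            report["experiments"].append({
                "label": exp.protein_label,
                "replicate": exp.replicate_id,
                "n_probes": len(exp),
                "primary_seed": str(fit.primary_seed),
                "secondary_seed": str(fit.secondary_seed) if fit.secondary_seed else None,
                "max_escore": float(np.nanmax(table["escore"].to_numpy())),
                "pattern_escores": pattern_scores,
            })

        # motif comparisons: replicate concordance within alleles, cross-allele
        comparisons = []
        n_rep = config.n_replicates
        groups = {config.reference.label: fits_by_exp[:n_rep],
                  config.variant.label: fits_by_exp[n_rep:]}
        for label, fits in groups.items():
            for i in range(len(fits) - 1):
                cmp_ = compare_pwms(fits[i].primary_trimmed,
                                    fits[i + 1].primary_trimmed)
                comparisons.append({
                    "kind": "replicate", "label": label,
                    "replicates": [i + 1, i + 2],
                    "mean_correlation": cmp_.mean_correlation,
                    "offset": cmp_.offset, "orientation": cmp_.orientation,
                })
        cmp_x = compare_pwms(fits_by_exp[0].primary_trimmed,
                             fits_by_exp[n_rep].primary_trimmed)
        comparisons.append({
            "kind": "cross-allele",
            "labels": [config.reference.label, config.variant.label],
            "mean_correlation": cmp_x.mean_correlation,
            "offset": cmp_x.offset, "orientation": cmp_x.orientation,
        })
        report["motif_comparisons"] = comparisons

        if config.emsa_inputs:
            emsa_section = {}
            fits = {}
            for label, path in config.emsa_inputs.items():
                curve = pio.read_emsa_table(path, protein_label=label)
                f = fit_kd(curve)
                fits[label] = f
                emsa_section[label] = {
                    "kd_nM": f.kd_nM, "f_max": f.f_max,
                    "rss": f.rss, "converged": f.converged,
                }
                log(f"EMSA {label}: Kd={f.kd_nM:.4g} nM")
            labels = list(fits)
            ratios = {}
            for i, la in enumerate(labels):
                for lb in labels[i + 1:]:
                    try:
                        ratios[f"{la}/{lb}"] = affinity_ratio(fits[la], fits[lb])
                    except ValueError:
                        ratios[f"{la}/{lb}"] = None
            report["emsa"] = {"fits": emsa_section, "kd_ratios": ratios}

        log_path = outdir / "run.log"
        log_path.write_text("\n".join(log_lines) + "\n")
        written.append(log_path)

        report["manifest"] = {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)
        }
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["patterns"] = list(d["patterns"])
    return d
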