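"""Readers and writers for the package's plain-text formats.

All tables are tab-separated with '#'-prefixed metadata/comment headers;
motifs are written in MEME minimal motif format (version 4), the lingua
franca of downstream motif tools.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ArrayDesign, Probe
from .motif import Pwm, information_content
from .simulate import BindingCurve, PbmExperiment

__all__ = [
    "write_design", "read_design",
    "write_probe_table", "read_probe_table",
    "write_escore_table", "read_escore_table",
    "write_meme", "read_meme",
    "write_ic_table",
    "read_emsa_table",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def write_design(design: ArrayDesign, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# coverage_k={design.coverage_k}\n")
        fh.write(f"# probe_length={design.probe_length}\n")
        fh.write("probe_id\tsequence\n")
        for p in design.probes:
            fh.write(f"{p.probe_id}\t{p.sequence}\n")


def read_design(path) -> ArrayDesign:
    meta, rows = _read_tsv(path, {"probe_id", "sequence"})
    probes = [Probe(r["probe_id"], r["sequence"]) for _, r in rows.iterrows()]
    return ArrayDesign(
        probes,
        coverage_k=int(meta.get("coverage_k", 10)),
        probe_length=len(probes[0].sequence) if probes else 36,
    )


def write_probe_table(experiment: PbmExperiment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# protein_label={experiment.protein_label}\n")
        fh.write(f"# replicate_id={experiment.replicate_id}\n")
        fh.write(f"# concentration_nM={experiment.concentration_nM:g}\n")
        fh.write("probe_id\tsequence\tintensity\n")
        for p in experiment.probes:
            fh.write(f"{p.probe_id}\t{p.sequence}\t{p.intensity!r}\n")


def read_probe_table(path) -> PbmExperiment:
    meta, rows = _read_tsv(path, {"probe_id", "sequence", "intensity"})
    seen: set[str] = set()
    probes = []
    for line_no, r in rows.iterrows():
        pid = str(r["probe_id"])
        if pid in seen:
            raise ParseError(f"{path}: line {line_no}: duplicate probe_id {pid!r}")
        seen.add(pid)
        try:
            inten = float(r["intensity"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: line {line_no}: bad intensity {r['intensity']!r}")
        if not inten > 0:
            raise ParseError(f"{path}: line {line_no}: non-positive intensity {inten}")
        try:
            probes.append(Probe(pid, str(r["sequence"]), inten))
        except ValueError as e:
            raise ParseError(f"{path}: line {line_no}: {e}")
    return PbmExperiment(
        probes,
        protein_label=meta.get("protein_label", ""),
        replicate_id=int(meta.get("replicate_id", 1)),
        concentration_nM=float(meta.get("concentration_nM", 300.0)),
    )


def _read_tsv(path, required: set[str]):
    """Parse a TSV with '# key=value' metadata lines; returns (meta, rows).

    Rows is a DataFrame of strings indexed by 1-based file line number.
    Handles CRLF transparently (universal newlines).
    """
    meta: dict[str, str] = {}
    header: list[str] | None = None
    records: list[list[str]] = []
    line_nos: list[int] = []
    with open(path, "r", newline=None) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                missing = required - set(header)
                if missing:
                    raise ParseError(
                        f"{path}: line {line_no}: missing columns {sorted(missing)}")
                continue
            if len(cells) != len(header):
                raise ParseError(
                    f"{path}: line {line_no}: expected {len(header)} fields, "
                    f"got {len(cells)}")
            records.append(cells)
            line_nos.append(line_no)
    if header is None:
        raise ParseError(f"{path}: no header line found")
    rows = pd.DataFrame(records, columns=header, index=line_nos)
    return meta, rows


def write_escore_table(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    """E-score TSV: kmer, escore, n_foreground, median_fg_intensity; NA for undefined."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("kmer\tescore\tn_foreground\tmedian_fg_intensity\n")
        for r in table.itertuples(index=False):
            e = "NA" if pd.isna(r.escore) else f"{r.escore:.6f}"
            m = "NA" if pd.isna(r.median_fg_intensity) else f"{r.median_fg_intensity:.6g}"
            fh.write(f"{r.kmer}\t{e}\t{r.n_foreground}\t{m}\n")


def read_escore_table(path) -> pd.DataFrame:
    _, rows = _read_tsv(path, {"kmer", "escore", "n_foreground", "median_fg_intensity"})
    return pd.DataFrame({
        "kmer": rows["kmer"].to_numpy(),
        "escore": pd.to_numeric(rows["escore"].replace("NA", np.nan)).to_numpy(),
        "n_foreground": rows["n_foreground"].astype(int).to_numpy(),
        "median_fg_intensity": pd.to_numeric(
            rows["median_fg_intensity"].replace("NA", np.nan)).to_numpy(),
    })


def write_meme(motifs: dict[str, Pwm], path) -> None:
    """MEME minimal motif format, one letter-probability block per motif."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for name, pwm in motifs.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, Pwm]:
    motifs: dict[str, Pwm] = {}
    name = None
    rows: list[list[float]] = []
    expect = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                expect = int(line.split("w=")[1].split()[0])
                rows = []
            elif expect and line and name is not None:
                rows.append([float(x) for x in line.split()])
                if len(rows) == expect:
                    mat = np.array(rows)
                    motifs[name] = Pwm(mat / mat.sum(axis=1, keepdims=True))
                    name, expect = None, 0
    return motifs


def write_ic_table(pwm: Pwm, path) -> None:
    ic = information_content(pwm)
    with open(path, "w") as fh:
        fh.write("position\tic_bits\tA\tC\tG\tT\n")
        for i, (bits, row) in enumerate(zip(ic, pwm.matrix)):
            fh.write(f"{i}\t{bits:.4f}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def read_emsa_table(path, probe_label: str = "", protein_label: str = "") -> BindingCurve:
    """EMSA lane table: concentration_nM, bound_intensity, unbound_intensity."""
    from .emsa import fraction_bound

    meta, rows = _read_tsv(
        path, {"concentration_nM", "bound_intensity", "unbound_intensity"})
    conc, pct = [], []
    for line_no, r in rows.iterrows():
        try:
            c = float(r["concentration_nM"])
            b = float(r["bound_intensity"])
            u = float(r["unbound_intensity"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: line {line_no}: non-numeric lane values")
        try:
            pct.append(fraction_bound(b, u))
        except ValueError as e:
            raise ParseError(f"{path}: line {line_no}: {e}")
        conc.append(c)
    return BindingCurve(
        np.asarray(conc), np.asarray(pct),
        probe_label=probe_label or meta.get("probe_label", ""),
        protein_label=protein_label or meta.get("protein_label", ""),
    )
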