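"""Plain-text file dialects used by the pipeline.

All artifacts are plain text: trace CSV (``time_s, pressure_mv,
temperature_c``), artifact-mask CSV (``start_s, end_s, label``),
expression TSV (``gene_id`` plus one column per sample, with a sidecar
sample→group TSV), BED3 peak files, gene-annotation TSV (``gene_id,
chrom, strand, tss_0based``) and JSON reports. Parse errors name the
file, line and field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .expr_de import DERecord, ExpressionMatrix
from .integrate import GeneAnnot, Peak, PeakGeneAssoc
from .pleth import BreathSeries, PressureTrace


class ParseError(ValueError):
    """A malformed row; message carries file, line and field."""

    def __init__(self, path, line: int | None, field: str, msg: str):
        self.path, self.line, self.field = str(path), line, field
        loc = f"{path}" + (f":{line}" if line is not None else "")
        super().__init__(f"{loc} [{field}]: {msg}")


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_trace_csv(trace: PressureTrace, path) -> None:
    t = trace.times_s
    temp = (
        trace.temperature_c
        if trace.temperature_c is not None
        else np.full(len(t), np.nan)
    )
    df = pd.DataFrame(
        {"time_s": t, "pressure_mv": trace.samples, "temperature_c": temp}
    )
    df.to_csv(path, index=False, float_format="%.8g")


def read_trace_csv(
    path,
    epochs: list[tuple[str, float, float]] | None = None,
    artifact_mask: list[tuple[float, float]] | None = None,
) -> PressureTrace:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "pressure_mv"):
        if col not in df.columns:
            raise ParseError(path, None, col, "missing required column")
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else None
            raise ParseError(path, line, col, "non-numeric value")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError(path, None, "time_s", "need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ParseError(path, None, "time_s", "sampling must be uniform")
    temp = (
        df["temperature_c"].to_numpy(dtype=float)
        if "temperature_c" in df.columns
        else None
    )
    return PressureTrace(
        samples=df["pressure_mv"].to_numpy(dtype=float),
        sampling_rate_hz=1.0 / dt[0],
        epochs=epochs or [],
        artifact_mask=artifact_mask or [],
        temperature_c=temp,
    )


def write_mask_csv(mask: list[tuple[float, float]], path, label: str = "artifact") -> None:
    pd.DataFrame(
        [(s, e, label) for s, e in mask], columns=["start_s", "end_s", "label"]
    ).to_csv(path, index=False)


def read_mask_csv(path) -> list[tuple[float, float]]:
    path = Path(path)
    df = pd.read_csv(path)
    out = []
    for i, row in df.iterrows():
        try:
            s, e = float(row["start_s"]), float(row["end_s"])
        except (ValueError, KeyError) as exc:
            raise ParseError(path, int(i) + 2, "start_s/end_s", str(exc)) from exc
        if not s < e:
            raise ParseError(path, int(i) + 2, "end_s", "interval start >= end")
        out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def write_expression_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.8g")


def read_expression_tsv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            pos = df.index.get_loc(bad[0]) + 2 if len(bad) else None
            raise ParseError(path, pos, col, "non-numeric expression value")
    if df.index.has_duplicates:
        raise ParseError(path, None, "gene_id", "duplicate gene ids")
    return df


def write_groups_tsv(groups: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(groups.items()), columns=["sample_id", "group"]
    ).to_csv(path, sep="\t", index=False)


def read_groups_tsv(path) -> dict[str, str]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    out: dict[str, str] = {}
    for i, row in df.iterrows():
        g = str(row["group"])
        if g not in ("case", "control"):
            raise ParseError(path, int(i) + 2, "group", f"unknown group {g!r}")
        out[str(row["sample_id"])] = g
    return out


def read_expression_matrix(matrix_path, groups_path) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=read_expression_tsv(matrix_path),
        group_labels=read_groups_tsv(groups_path),
    )


def write_de_tsv(records: list[DERecord], path) -> None:
    rows = []
    for r in records:
        call = "ns"
        if r.fdr < 0.05 and r.signed_fc >= 1.2:
            call = "up"
        elif r.fdr < 0.05 and r.signed_fc <= -1.2:
            call = "down"
        rows.append(
            (r.gene_id, r.log2fc, r.signed_fc, r.t_stat, r.p, r.fdr, call)
        )
    pd.DataFrame(
        rows, columns=["gene_id", "log2fc", "signed_fc", "t", "p", "fdr", "call"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# genomic intervals
# ---------------------------------------------------------------------------


def write_bed(peaks: pd.DataFrame | list[Peak], path) -> None:
    if isinstance(peaks, pd.DataFrame):
        rows = peaks[["chrom", "start", "end"]].itertuples(index=False)
    else:
        rows = ((p.chrom, p.start, p.end) for p in peaks)
    with open(path, "w") as fh:
        for chrom, start, end in rows:
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")


def read_bed(path) -> list[Peak]:
    path = Path(path)
    out: list[Peak] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, i, "row", "BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(path, i, "start/end", str(exc)) from exc
            if start < 0:
                raise ParseError(path, i, "start", "negative coordinate")
            if start >= end:
                raise ParseError(path, i, "end", "start >= end")
            out.append(Peak(chrom=parts[0], start=start, end=end))
    return out


def write_gene_annot_tsv(genes: pd.DataFrame | list[GeneAnnot], path) -> None:
    if isinstance(genes, list):
        genes = pd.DataFrame(
            [(g.gene_id, g.chrom, g.strand, g.tss) for g in genes],
            columns=["gene_id", "chrom", "strand", "tss_0based"],
        )
    genes[["gene_id", "chrom", "strand", "tss_0based"]].to_csv(
        path, sep="\t", index=False
    )


def read_gene_annot_tsv(path) -> list[GeneAnnot]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    out: list[GeneAnnot] = []
    for i, row in df.iterrows():
        strand = str(row["strand"])
        if strand not in ("+", "-"):
            raise ParseError(path, int(i) + 2, "strand", f"bad strand {strand!r}")
        try:
            tss = int(row["tss_0based"])
        except ValueError as exc:
            raise ParseError(path, int(i) + 2, "tss_0based", str(exc)) from exc
        if tss < 0:
            raise ParseError(path, int(i) + 2, "tss_0based", "negative TSS")
        out.append(
            GeneAnnot(gene_id=str(row["gene_id"]), chrom=str(row["chrom"]), strand=strand, tss=tss)
        )
    if len({g.gene_id for g in out}) != len(out):
        raise ParseError(path, None, "gene_id", "duplicate gene ids")
    return out


def write_assoc_tsv(assocs: list[PeakGeneAssoc], path) -> None:
    pd.DataFrame(
        [
            (a.peak.chrom, a.peak.start, a.peak.end, a.gene_id, a.signed_distance_bp)
            for a in assocs
        ],
        columns=["chrom", "start", "end", "gene_id", "signed_distance_bp"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------


def write_breaths_tsv(series: BreathSeries, path) -> None:
    pd.DataFrame(
        [
            (b.onset_s, b.peak_s, b.amplitude_mv, b.volume_ul)
            for b in series.breaths
        ],
        columns=["onset_s", "peak_s", "amplitude_mv", "volume_ul"],
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
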