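"""Reading and writing of IS, TE, CIS and gene-atmosphere tables.

Input tables are delimited text (TSV/CSV with a header) or BED. Mandatory IS
columns: chromosome, insertion position, entropy label. Mandatory TE columns:
chromosome, transcription start site (a BioMart-export-like shape); the name
column is optional and auto-generated when absent.

Output tables are TSV with ``#``-prefixed provenance header lines; readers
here skip those, so write -> read round-trips are exact.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import DatasetError, RowError, SchemaError
from .types import (
    CIS,
    GALink,
    GeneAtmosphere,
    IntegrationSite,
    TranscriptionalElement,
    chrom_sort_key,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

# accepted header spellings, lower-cased and stripped
_CHROM_ALIASES = {"chrom", "chromosome", "chr", "chromosome number", "chromosome name"}
_POS_ALIASES = {"pos", "position", "insertion site position", "insertion_position",
                "integration position", "location"}
_LABEL_ALIASES = {"label", "entropy label", "entropy_label", "tumor type",
                  "virus type", "factor"}
_TSS_ALIASES = {"tss", "transcription start site", "transcription_start_site",
                "transcript start (bp)", "gene start (bp)", "start"}
_NAME_ALIASES = {"name", "gene", "gene name", "associated gene name",
                 "gene symbol", "symbol", "te name"}

_SEP = {"tsv": "\t", "csv": ","}


def _infer_dialect(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect.lower()
    suffix = Path(path).suffix.lower()
    return {".csv": "csv", ".bed": "bed"}.get(suffix, "tsv")


def _resolve(columns: Sequence[str], aliases: set[str], what: str) -> str:
    lowered = {str(c).strip().lower(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    raise SchemaError(
        f"missing mandatory column '{what}' (accepted names: "
        f"{', '.join(sorted(aliases))}; found: {', '.join(map(str, columns))})"
    )


def _read_delimited(path: str | Path, dialect: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=_SEP[dialect], comment="#", dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise DatasetError(f"empty input file: {path}") from None
    if df.empty:
        raise DatasetError(f"no data rows in input file: {path}")
    return df


def _read_bed(path: str | Path, min_cols: int) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise DatasetError(f"empty BED file: {path}")
    width = max(len(r) for r in rows)
    if width < min_cols:
        raise SchemaError(f"BED file needs >= {min_cols} columns, found {width}")
    cols = ["chrom", "start", "end", "name", "score", "strand"][:width]
    return pd.DataFrame([r + [""] * (width - len(r)) for r in rows], columns=cols)


def _to_int(value: str, row: int, what: str) -> int:
    try:
        return int(str(value).strip())
    except (TypeError, ValueError):
        raise RowError(f"non-integer {what}: {value!r}", row=row) from None


def read_is_table(
    path: str | Path,
    dialect: str | None = None,
    strip_chr_prefix: bool = False,
    label_from: str = "name",
    bed_zero_based: bool = True,
) -> list[IntegrationSite]:
    """Read an integration-site table, returning sites sorted by (chrom, pos).

    Parameters
    ----------
    path : path to a TSV/CSV (header required) or BED file.
    dialect : "tsv", "csv" or "bed"; inferred from the extension when None.
    strip_chr_prefix : normalise "chr1" -> "1" on read.
    label_from : BED only — field carrying the entropy label (default the
        BED name field).
    bed_zero_based : BED only — convert 0-based half-open starts to 1-based
        positions (position = start + 1). Disable for sources already
        exporting 1-based starts.

    Duplicate (chrom, pos, label) rows are retained as distinct sites and
    counted in a log message; the method never deduplicates.
    """
    dialect = _infer_dialect(path, dialect)
    if dialect == "bed":
        df = _read_bed(path, min_cols=3)
        offset = 1 if bed_zero_based else 0
        sites = []
        for i, rec in enumerate(df.itertuples(index=False), start=1):
            pos = _to_int(rec.start, i, "position") + offset
            label = str(getattr(rec, label_from, "") or "").strip()
            if not label:
                raise RowError(f"empty entropy label (field '{label_from}')", row=i)
            if pos < 1:
                raise RowError(f"position must be >= 1, got {pos}", row=i)
            sites.append(IntegrationSite(
                normalize_chrom(rec.chrom, strip_chr_prefix), pos, label, i - 1))
    else:
        df = _read_delimited(path, dialect)
        c_chrom = _resolve(df.columns, _CHROM_ALIASES, "chromosome")
        c_pos = _resolve(df.columns, _POS_ALIASES, "insertion position")
        c_label = _resolve(df.columns, _LABEL_ALIASES, "entropy label")
        sites = []
        for i, (chrom, pos, label) in enumerate(
                zip(df[c_chrom], df[c_pos], df[c_label]), start=1):
            p = _to_int(pos, i, "position")
            if p < 1:
                raise RowError(f"position must be >= 1, got {p}", row=i)
            if label is None or not str(label).strip():
                raise RowError("empty entropy label", row=i)
            sites.append(IntegrationSite(
                normalize_chrom(chrom, strip_chr_prefix), p, str(label).strip(),
                i - 1))

    sites.sort(key=lambda s: s.sort_key)
    n_dup = len(sites) - len({(s.chrom, s.pos, s.label) for s in sites})
    if n_dup:
        logger.info("retained %d duplicate (chrom, pos, label) site rows", n_dup)
    return sites


def read_te_table(
    path: str | Path,
    dialect: str | None = None,
    strip_chr_prefix: bool = False,
    bed_zero_based: bool = True,
) -> list[TranscriptionalElement]:
    """Read an annotation table of transcriptional elements, sorted by
    (chrom, tss).

    For BED input the TSS is the 5' end of the feature: start + 1 on the
    plus (or missing) strand, the end coordinate on the minus strand.
    Missing or empty names are auto-filled as ``TE_<k>`` in input order.
    """
    dialect = _infer_dialect(path, dialect)
    tes = []
    if dialect == "bed":
        df = _read_bed(path, min_cols=3)
        for i, rec in enumerate(df.itertuples(index=False), start=1):
            start = _to_int(rec.start, i, "start")
            end = _to_int(rec.end, i, "end")
            strand = str(getattr(rec, "strand", "") or "+").strip()
            tss = end if strand == "-" else start + (1 if bed_zero_based else 0)
            if tss < 1:
                raise RowError(f"TSS must be >= 1, got {tss}", row=i)
            name = str(getattr(rec, "name", "") or "").strip()
            if not name or name == ".":
                name = f"TE_{i}"
            tes.append(TranscriptionalElement(
                normalize_chrom(rec.chrom, strip_chr_prefix), tss, name))
    else:
        df = _read_delimited(path, dialect)
        c_chrom = _resolve(df.columns, _CHROM_ALIASES, "chromosome")
        c_tss = _resolve(df.columns, _TSS_ALIASES, "transcription start site")
        lowered = {str(c).strip().lower(): c for c in df.columns}
        c_name = next((lowered[a] for a in _NAME_ALIASES if a in lowered), None)
        for i, rec in enumerate(df.itertuples(index=False), start=1):
            row = dict(zip(df.columns, rec))
            tss = _to_int(row[c_tss], i, "TSS")
            if tss < 1:
                raise RowError(f"TSS must be >= 1, got {tss}", row=i)
            name = str(row[c_name]).strip() if c_name is not None else ""
            if not name or name.lower() == "nan":
                name = f"TE_{i}"
            tes.append(TranscriptionalElement(
                normalize_chrom(row[c_chrom], strip_chr_prefix), tss, name))

    tes.sort(key=lambda t: t.sort_key)
    return tes


CIS_COLUMNS = [
    "cis_number", "cis_name", "chrom", "order", "dimension",
    "avg_pos", "median_pos", "n_labels", "entropy", "norm_entropy",
    "p_value", "loglik_ratio", "is_positions", "is_labels",
]


def _header_lines(params: dict | None) -> list[str]:
    if not params:
        return []
    return [f"# {k}={v}" for k, v in sorted(params.items())]


def write_cis_table(cis_list: Iterable[CIS], path: str | Path,
                    params: dict | None = None) -> None:
    """Write one TSV row per CIS with its full statistics record.

    ``params`` key/value pairs are echoed as ``#`` header lines for
    provenance (threshold, seed, null model, ...).
    """
    rows = []
    for cis in cis_list:
        st = cis.stats
        if st is None:
            raise DatasetError(f"CIS {cis.name} has no computed statistics")
        rows.append({
            "cis_number": cis.number,
            "cis_name": cis.name,
            "chrom": cis.chrom,
            "order": st.order,
            "dimension": st.dimension,
            "avg_pos": f"{st.avg_pos:.1f}",
            "median_pos": f"{st.median_pos:.1f}",
            "n_labels": st.n_labels,
            "entropy": f"{st.entropy:.6f}",
            "norm_entropy": f"{st.norm_entropy:.6f}",
            "p_value": f"{st.p_value:.6e}",
            "loglik_ratio": f"{st.loglik_ratio:.6f}",
            "is_positions": ",".join(str(p) for p in cis.positions),
            "is_labels": ",".join(m.label for m in cis.members),
        })
        if st.fdr_q is not None:
            rows[-1]["fdr_q"] = f"{st.fdr_q:.6e}"
    columns = CIS_COLUMNS + (["fdr_q"] if rows and "fdr_q" in rows[0] else [])
    _write_tsv(path, columns, rows, params)


def read_cis_table(path: str | Path) -> pd.DataFrame:
    """Read back a CIS TSV written by :func:`write_cis_table`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in CIS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"not a CIS table, missing columns: {missing}")
    return df


GA_COLUMNS = ["cis_name", "is_row_id", "is_pos", "te_name", "tss", "distance"]


def write_ga_table(ga_list: Iterable[GeneAtmosphere], path: str | Path,
                   params: dict | None = None) -> None:
    """Write one TSV row per (CIS, IS, TE) proximity link."""
    rows = [{
        "cis_name": ga.cis_ref,
        "is_row_id": ln.site.row_id,
        "is_pos": ln.site.pos,
        "te_name": ln.te.name,
        "tss": ln.te.tss,
        "distance": ln.distance,
    } for ga in ga_list for ln in ga.links]
    _write_tsv(path, GA_COLUMNS, rows, params)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    """One gene symbol per line — directly usable as enrichment-tool input."""
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_cis_bed(cis_list: Iterable[CIS], path: str | Path) -> None:
    """Export CIS intervals as BED4 (0-based half-open) for genome browsers."""
    with open(path, "w", newline="") as fh:
        for cis in cis_list:
            fh.write(f"{cis.chrom}\t{cis.first - 1}\t{cis.last}\t{cis.name}\n")


def _write_tsv(path: str | Path, columns: list[str], rows: list[dict],
               params: dict | None) -> None:
    with open(path, "w", newline="") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t",
                                lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def write_is_table(sites: Iterable[IntegrationSite], path: str | Path,
                   params: dict | None = None) -> None:
    """Write sites in the canonical three-column input shape."""
    rows = [{"chrom": s.chrom, "pos": s.pos, "label": s.label} for s in sites]
    _write_tsv(path, ["chrom", "pos", "label"], rows, params)


def write_te_table(tes: Iterable[TranscriptionalElement], path: str | Path,
                   params: dict | None = None) -> None:
    rows = [{"chrom": t.chrom, "tss": t.tss, "name": t.name} for t in tes]
    _write_tsv(path, ["chrom", "tss", "name"], rows, params)
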