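"""Readers and writers for the package's tab-separated dialects.

All tables are UTF-8, tab-separated, with a header row.  Floats are
serialized with ``repr`` precision so a write-then-read round trip
reproduces in-memory values bit for bit; parsing is locale-independent
(C-locale decimal point).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO

from .enrichment import EnrichmentResult, GoMapping
from .errors import InvalidInputError
from .model import CountQuartet, GlmFit, LibrarySizes
from .qc import OhrDistribution, OrthologHit
from .ranking import ExpressionCall, RankedResult

PathLike = Union[str, Path]

COUNT_HEADER = ["contig_id", "r1", "s1", "r2", "s2"]
FIT_HEADER = [
    "contig_id", "fc_main", "log2fc", "alfca", "se_gamma", "z", "p",
    "beta_batch", "delta", "estimable", "corrected",
]
CALL_HEADER = ["contig_id", "call_resistant", "call_susceptible", "unique_in"]
ENRICH_HEADER = ["go_term", "a", "b", "c", "d", "p", "q", "direction"]
BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
_LIB_KEYS = ("r1", "s1", "r2", "s2")


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------- counts

def read_count_table(path: PathLike) -> list[CountQuartet]:
    """Parse a count table: header ``contig_id  r1  s1  r2  s2``."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if header.rstrip("\n").split("\t") != COUNT_HEADER:
            raise InvalidInputError(
                f"{path}: expected header {chr(9).join(COUNT_HEADER)!r}"
            )
        quartets = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            cid, *raw = fields
            try:
                counts = [int(v) for v in raw]
            except ValueError:
                raise InvalidInputError(
                    f"{path}:{lineno}: non-integer count in {raw}"
                ) from None
            try:
                quartets.append(CountQuartet(cid, *counts))
            except InvalidInputError as exc:
                raise InvalidInputError(f"{path}:{lineno}: {exc}") from None
    if not quartets:
        warnings.warn(f"{path}: count table has no data rows", stacklevel=2)
    return quartets


def write_count_table(quartets: Iterable[CountQuartet], path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(COUNT_HEADER) + "\n")
        for q in quartets:
            fh.write(
                f"{q.contig_id}\t{q.y_r1}\t{q.y_s1}\t{q.y_r2}\t{q.y_s2}\n"
            )


# ---------------------------------------------------------- library sizes

def read_library_sizes(path: PathLike) -> LibrarySizes:
    """Two-column file ``sample<TAB>total_reads`` with keys r1 s1 r2 s2."""
    path = Path(path)
    values: dict[str, float] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 'sample<TAB>total_reads'"
                )
            key, raw = fields
            if key == "sample":
                continue  # optional header
            if key not in _LIB_KEYS:
                raise InvalidInputError(
                    f"{path}:{lineno}: unknown sample key {key!r} "
                    f"(expected one of {_LIB_KEYS})"
                )
            if key in values:
                raise InvalidInputError(f"{path}:{lineno}: duplicate key {key}")
            try:
                values[key] = float(raw)
            except ValueError:
                raise InvalidInputError(
                    f"{path}:{lineno}: non-numeric total {raw!r}"
                ) from None
    missing = [k for k in _LIB_KEYS if k not in values]
    if missing:
        raise InvalidInputError(f"{path}: missing sample keys {missing}")
    return LibrarySizes(*(values[k] for k in _LIB_KEYS))


def write_library_sizes(libs: LibrarySizes, path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample\ttotal_reads\n")
        for key, value in zip(_LIB_KEYS, libs.totals()):
            fh.write(f"{key}\t{_fmt(value)}\n")


# ------------------------------------------------------------------ fits

def write_fits_table(fits: Iterable[GlmFit], path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(FIT_HEADER) + "\n")
        for f in fits:
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        _fmt(f.fc_main), _fmt(f.log2fc), _fmt(f.alfca),
                        _fmt(f.se_gamma), _fmt(f.z), _fmt(f.p),
                        _fmt(f.beta_batch), _fmt(f.delta),
                        str(f.estimable), str(f.corrected),
                    ]
                )
                + "\n"
            )


def read_fits_table(path: PathLike) -> list[GlmFit]:
    import math

    path = Path(path)
    fits = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != FIT_HEADER:
            raise InvalidInputError(f"{path}: unexpected fits header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(FIT_HEADER):
                raise InvalidInputError(
                    f"{path}:{lineno}: expected {len(FIT_HEADER)} fields"
                )
            cid, fc, log2fc, alfca, se, z, p, beta, delta, est, cor = fields
            log2fc_f = float(log2fc)
            fits.append(
                GlmFit(
                    contig_id=cid,
                    alpha=float("nan"),  # not serialized
                    beta_batch=float(beta),
                    gamma=log2fc_f * math.log(2.0),
                    delta=float(delta),
                    se_gamma=float(se),
                    z=float(z),
                    p=float(p),
                    fc_main=float(fc),
                    log2fc=log2fc_f,
                    alfca=float(alfca),
                    estimable=est == "True",
                    corrected=cor == "True",
                )
            )
    return fits


def write_ranked_table(ranked: Iterable[RankedResult], path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("rank\tdirection\t" + "\t".join(FIT_HEADER) + "\n")
        for r in ranked:
            f = r.fit
            fh.write(
                "\t".join(
                    [
                        str(r.rank), r.direction, f.contig_id,
                        _fmt(f.fc_main), _fmt(f.log2fc), _fmt(f.alfca),
                        _fmt(f.se_gamma), _fmt(f.z), _fmt(f.p),
                        _fmt(f.beta_batch), _fmt(f.delta),
                        str(f.estimable), str(f.corrected),
                    ]
                )
                + "\n"
            )


# ------------------------------------------------------- screen / enrich

def write_calls_table(calls: Iterable[ExpressionCall], path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(CALL_HEADER) + "\n")
        for c in calls:
            fh.write(
                f"{c.contig_id}\t{c.call_resistant}\t{c.call_susceptible}"
                f"\t{c.unique_in}\n"
            )


def read_go_mapping(path: PathLike) -> GoMapping:
    """Two-column ``contig_id<TAB>GO:NNNNNNN``, one association per line."""
    path = Path(path)
    pairs = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 'contig_id<TAB>GO:NNNNNNN'"
                )
            pairs.append((fields[0], fields[1]))
    try:
        return GoMapping(pairs)
    except InvalidInputError as exc:
        raise InvalidInputError(f"{path}: {exc}") from None


def write_go_mapping(mapping: GoMapping, path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for gene, term in mapping.pairs():
            fh.write(f"{gene}\t{term}\n")


def read_id_set(path: PathLike) -> set[str]:
    """One contig id per line; blank lines and ``#`` comments ignored."""
    ids = set()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return ids


def write_id_set(ids: Iterable[str], path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for cid in sorted(ids):
            fh.write(cid + "\n")


def write_enrichment_table(
    results: Iterable[EnrichmentResult], path: PathLike
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(ENRICH_HEADER) + "\n")
        for r in results:
            t = r.table
            fh.write(
                f"{r.go_term_id}\t{t.a}\t{t.b}\t{t.c}\t{t.d}"
                f"\t{_fmt(r.p)}\t{_fmt(r.q)}\t{r.enriched_direction}\n"
            )


# -------------------------------------------------------------------- qc

def contig_lengths_from_fasta(path: PathLike) -> list[int]:
    """Sequence lengths from a (wrapped or unwrapped) FASTA file."""
    lengths = [len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not lengths:
        raise InvalidInputError(f"{path}: no FASTA records found")
    return lengths


def read_subject_lengths(path: PathLike) -> dict[str, int]:
    """Two-column ``subject_id<TAB>subject_length`` table."""
    path = Path(path)
    lengths: dict[str, int] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2 or fields[0] == "subject_id":
                if fields[0] == "subject_id":
                    continue
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 'subject_id<TAB>length'"
                )
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError:
                raise InvalidInputError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from None
    if not lengths:
        raise InvalidInputError(f"{path}: no subject lengths found")
    return lengths


def read_blast_tabular(
    path: PathLike, subject_lengths: dict[str, int]
) -> list[OrthologHit]:
    """12-column BLAST tabular (outfmt 6) to ortholog hits.

    Aligned subject span is ``abs(send - sstart) + 1`` (minus-strand
    hits report descending subject coordinates).
    """
    df = pd.read_csv(
        path, sep="\t", names=BLAST_COLUMNS, header=None, comment="#",
        dtype={"qseqid": str, "sseqid": str},
    )
    if df.shape[1] != 12:
        raise InvalidInputError(f"{path}: expected 12 tab-separated columns")
    hits = []
    for row in df.itertuples(index=False):
        if row.sseqid not in subject_lengths:
            raise InvalidInputError(
                f"{path}: subject {row.sseqid} missing from lengths table"
            )
        hits.append(
            OrthologHit(
                query_id=row.qseqid,
                subject_id=row.sseqid,
                subject_length=subject_lengths[row.sseqid],
                aligned_subject_span=abs(int(row.send) - int(row.sstart)) + 1,
                bitscore=float(row.bitscore),
                evalue=float(row.evalue),
            )
        )
    return hits


def write_ohr_table(
    per_query: dict[str, OrthologHit], path: PathLike
) -> None:
    from .qc import ortholog_hit_ratio

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("query_id\tsubject_id\tohr\n")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for qid in sorted(per_query):
                h = per_query[qid]
                fh.write(f"{qid}\t{h.subject_id}\t{_fmt(ortholog_hit_ratio(h))}\n")


def write_ohr_summary(dist: OhrDistribution, path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("bin_low\tbin_high\tfraction\n")
        for lo, hi, frac in zip(
            dist.bin_edges[:-1], dist.bin_edges[1:], dist.fractions
        ):
            fh.write(f"{_fmt(lo)}\t{_fmt(hi)}\t{_fmt(frac)}\n")
        fh.write(f"# frac_above_0.8\t{_fmt(dist.frac_above_0_8)}\n")
        fh.write(f"# frac_above_0.5\t{_fmt(dist.frac_above_0_5)}\n")
        fh.write(f"# n_queries\t{dist.n_queries}\n")
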