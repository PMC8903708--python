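"""Readers and writers for the external formats the pipeline touches.

Conventions: all coordinates are 1-based inclusive (GTF style); circular
coordinates run 1..L with position 1 the first nucleotide downstream of the
back-splice junction; expression TSVs carry linear-scale values (log
transforms happen inside the analysis stages).  Readers reject malformed
input rather than coerce it, and every writer/reader pair round-trips
bit-identically for valid data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from circscreen.circorf import CircularTranscript
from circscreen.errors import ParseError


@dataclass
class ExpressionDataset:
    """Probe x sample linear-scale expression with sample group labels."""

    values: pd.DataFrame  # probes (rows) x samples (columns)
    groups: dict[str, str]  # sample id -> group name
    truth: Optional[dict] = None  # simulation ground truth, if any

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate probe id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ParseError(f"samples without a group annotation: {missing}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ParseError("expression values must be finite")
        if (arr < 0).any():
            raise ParseError("expression values must be non-negative")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def subset_probes(self, probes) -> "ExpressionDataset":
        return ExpressionDataset(
            values=self.values.loc[list(probes)], groups=dict(self.groups), truth=self.truth
        )


@dataclass
class TranscriptModel:
    """Exon structure of one transcript: ordered 1-based inclusive intervals."""

    transcript_id: str
    exons: list[tuple[int, int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParseError(f"{self.transcript_id}: strand must be + or -")
        exons = sorted(self.exons)
        for s, e in exons:
            if s > e:
                raise ParseError(f"{self.transcript_id}: exon ({s},{e}) has start > end")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ParseError(
                    f"{self.transcript_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )
        self.exons = exons


@dataclass
class SurvivalTable:
    """Per-subject survival data: time (months), event indicator, expression."""

    table: pd.DataFrame  # columns: subject_id, time, event, expression

    def __post_init__(self) -> None:
        required = ["subject_id", "time", "event", "expression"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ParseError(f"survival table missing columns {missing}")
        if (self.table["time"] <= 0).any():
            raise ParseError("survival times must be positive")
        if not self.table["event"].isin([0, 1]).all():
            raise ParseError("event indicator must be 0 or 1")

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    @property
    def expression(self) -> np.ndarray:
        return self.table["expression"].to_numpy(dtype=float)


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit identifier universe."""

    sets: dict[str, list[str]]
    universe: list[str]
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for name, members in self.sets.items():
            outside = sorted(set(members) - uni)
            if outside:
                raise ParseError(f"set {name!r} has members outside the universe: {outside[:5]}")


# ---------------------------------------------------------------------------
# expression TSV


def read_expression(path: str, annotation_path: str) -> ExpressionDataset:
    """Read a probe x sample TSV (header = sample ids, first column = probe
    ids) plus a sample->group annotation TSV with columns sample, group."""
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for j, col in enumerate(values.columns):
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna() & values[col].notna()
        if bad.any():
            row = values.index[bad.argmax()]
            raise ParseError(f"{path}: non-numeric cell at probe {row!r}, sample {col!r}")
        values[col] = coerced
    if values.isna().any().any():
        raise ParseError(f"{path}: missing values are not allowed")
    values.index.name = None
    values.columns.name = None
    ann = pd.read_csv(annotation_path, sep="\t")
    if not {"sample", "group"}.issubset(ann.columns):
        raise ParseError(f"{annotation_path}: expected columns 'sample' and 'group'")
    groups = dict(zip(ann["sample"].astype(str), ann["group"].astype(str)))
    missing = [s for s in values.columns if s not in groups]
    if missing:
        raise ParseError(f"{annotation_path}: no group for samples {missing}")
    return ExpressionDataset(values=values, groups=groups)


def write_expression(data: ExpressionDataset, path: str, annotation_path: str) -> None:
    data.values.to_csv(path, sep="\t", index_label="probe_id")
    ann = pd.DataFrame(
        {"sample": data.sample_ids, "group": [data.groups[s] for s in data.sample_ids]}
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# circular FASTA

_IRES_RE = re.compile(r"^ires=(\d+)-(\d+)$")


def read_fasta_circular(path: str) -> list[CircularTranscript]:
    """Read FASTA whose headers may carry ``circular=true`` and
    ``ires=START-END`` tokens (1-based inclusive circular coordinates)."""
    out: list[CircularTranscript] = []
    for rec in SeqIO.parse(path, "fasta"):
        circular = False
        ires = None
        for token in rec.description.split()[1:]:
            if token.lower() == "circular=true":
                circular = True
            else:
                m = _IRES_RE.match(token.lower())
                if m:
                    s, e = int(m.group(1)), int(m.group(2))
                    if s < 1 or e < s or e > len(rec.seq):
                        raise ParseError(
                            f"{path}: record {rec.id!r} IRES {s}-{e} outside 1..{len(rec.seq)}"
                        )
                    ires = (s, e)
        out.append(
            CircularTranscript(
                id=rec.id, sequence=str(rec.seq), circular=circular, ires=ires
            )
        )
    return out


def write_fasta_circular(transcripts: list[CircularTranscript], path: str) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            tokens = [t.id]
            if t.circular:
                tokens.append("circular=true")
            if t.ires is not None:
                tokens.append(f"ires={t.ires[0]}-{t.ires[1]}")
            fh.write(">" + " ".join(tokens) + "\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GTF transcript models


def read_transcript_models(path: str) -> list[TranscriptModel]:
    """Parse exon features of a GTF into per-transcript exon models."""
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, TranscriptModel] = {}
    order: list[str] = []
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise ParseError(f"{path}: exon at {feat.seqid}:{feat.start} lacks transcript_id")
        tid = tids[0]
        if tid not in by_tx:
            by_tx[tid] = TranscriptModel(transcript_id=tid, exons=[], strand=feat.strand)
            order.append(tid)
        by_tx[tid].exons.append((feat.start, feat.end))
    models = []
    for tid in order:
        m = by_tx[tid]
        models.append(TranscriptModel(transcript_id=tid, exons=m.exons, strand=m.strand))
    return models


def write_transcript_models(models: list[TranscriptModel], path: str, seqid: str = "chr1") -> None:
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                attrs = f'gene_id "{m.transcript_id}_gene"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{seqid}\tcircscreen\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# survival CSV


def read_survival(path: str) -> SurvivalTable:
    df = pd.read_csv(path)
    return SurvivalTable(table=df)


def write_survival(table: SurvivalTable, path: str) -> None:
    table.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT-like: name <TAB> description <TAB> member...)

_UNIVERSE_SET = "__UNIVERSE__"


def read_genesets(path: str) -> GeneSetCollection:
    """Read a GMT-like file.  A record named ``__UNIVERSE__`` supplies the
    identifier universe; absent that, the universe is the union of all sets."""
    sets: dict[str, list[str]] = {}
    universe: Optional[list[str]] = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{ln}: expected name, description, members")
            name, _desc, members = fields[0], fields[1], fields[2:]
            if name == _UNIVERSE_SET:
                universe = members
            else:
                sets[name] = members
    if universe is None:
        seen: list[str] = []
        for members in sets.values():
            for g in members:
                if g not in seen:
                    seen.append(g)
        universe = seen
    return GeneSetCollection(sets=sets, universe=universe)


def write_genesets(coll: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([_UNIVERSE_SET, "universe"] + list(coll.universe)) + "\n")
        for name, members in coll.sets.items():
            fh.write("\t".join([name, "."] + list(members)) + "\n")
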