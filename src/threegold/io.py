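"""Sequence and table input/output.

Reads FASTA/FASTQ (via Biopython) and the plain one-sequence-per-line text
format; writes cluster assignments and evaluation reports as TSV.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

FORMATS = ("fasta", "fastq", "lines")
_EXT = {
    ".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
    ".fq": "fastq", ".fastq": "fastq",
    ".txt": "lines", ".lines": "lines", ".seqs": "lines",
}

SINGLETON_LABEL = "SINGLETON"


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str


def detect_format(path: str | Path) -> str:
    return _EXT.get(Path(path).suffix.lower(), "lines")


def read_sequences(path: str | Path, fmt: str | None = None) -> list[SequenceRecord]:
    """Load sequences in file order, uppercased; FASTQ qualities discarded.

    The ``lines`` format auto-assigns ids "1", "2", ... by line number.
    """
    fmt = fmt or detect_format(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    records: list[SequenceRecord] = []
    if fmt == "lines":
        with open(path) as fh:
            for k, line in enumerate(fh, start=1):
                seq = line.strip().upper()
                if seq:
                    records.append(SequenceRecord(str(k), seq))
    else:
        for rec in SeqIO.parse(str(path), fmt):
            records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"no sequences found in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sequence ids in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")


def write_clusters(cluster_set, path: str | Path) -> None:
    """TSV with one row per member plus SINGLETON rows."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tcentroid_id\tmember_id\tdistance\n")
        for k, cl in enumerate(cluster_set.clusters, start=1):
            for m in cl.member_ids:
                d = cl.member_distances.get(m, 0.0)
                fh.write(f"cluster_{k}\t{cl.centroid_id}\t{m}\t{d:g}\n")
        for s in cluster_set.singletons:
            fh.write(f"{SINGLETON_LABEL}\t{s}\t{s}\t0\n")


def read_clusters(path: str | Path):
    """Inverse of :func:`write_clusters` (round-trips exactly)."""
    from .clustering import Cluster, ClusterSet  # deferred: avoids an import cycle

    clusters: dict[str, Cluster] = {}
    singletons: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["cluster_id", "centroid_id", "member_id"]:
            raise ValueError(f"{path} is not a cluster TSV")
        for line in fh:
            cid, centroid, member, dist = line.rstrip("\n").split("\t")
            if cid == SINGLETON_LABEL:
                singletons.append(member)
                continue
            cl = clusters.setdefault(cid, Cluster(centroid, [], {}))
            cl.member_ids.append(member)
            cl.member_distances[member] = float(dist)
    return ClusterSet(list(clusters.values()), singletons)


def write_truth(truth: dict[str, list[str]], path: str | Path) -> None:
    """Reference clusters as TSV (cluster_id, member_id)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember_id\n")
        for cid, members in truth.items():
            for m in members:
                fh.write(f"{cid}\t{m}\n")


def read_truth(path: str | Path) -> dict[str, list[str]]:
    truth: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["cluster_id", "member_id"]:
            raise ValueError(f"{path} is not a reference-cluster TSV")
        for line in fh:
            cid, member = line.rstrip("\n").split("\t")[:2]
            truth.setdefault(cid, []).append(member)
    return truth


def write_report(report, path: str | Path) -> None:
    """Evaluation report TSV: one row per reference cluster plus totals."""
    with open(path, "w") as fh:
        fh.write(
            "reference_id\tmatched_centroid\tref_size\texp_size\t"
            "sensitivity\tspecificity\tqualified\n"
        )
        for row in report.rows:
            fh.write(
                f"{row.reference_id}\t{row.matched_centroid or '-'}\t{row.ref_size}\t"
                f"{row.exp_size}\t{row.sensitivity:.2f}\t{row.specificity:.2f}\t"
                f"{'yes' if row.qualified else 'no'}\n"
            )
        fh.write(
            f"#total_clustered={report.total_clustered}\t"
            f"singletons={report.n_singletons}\t"
            f"qualified_clusters={report.n_qualified}\t"
            f"size_range={report.size_range[0]}-{report.size_range[1]}\n"
        )


def log(msg: str) -> None:
    print(msg, file=sys.stderr)
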