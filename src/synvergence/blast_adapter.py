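"""Optional adapter to the BLAST+ binaries (blastp / tblastn).

The pipeline's logic is engine-independent: this adapter only changes where
Hit records come from.  Everything ships and tests on the built-in engine;
the adapter is used when the binaries are on PATH, e.g. to cross-check
hit/no-hit concordance.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .genome_model import write_fasta
from .simsearch import Hit

__all__ = ["blast_available", "blastp_search", "tblastn_search", "write_hits_tsv", "read_hits_tsv"]


def blast_available() -> bool:
    return all(shutil.which(t) for t in ("makeblastdb", "blastp", "tblastn"))


def _run_blast(
    tool: str, queries: dict[str, str], subjects: dict[str, str], dbtype: str, cutoff: float
) -> list[Hit]:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        qf, sf = tmp / "q.fa", tmp / "s.fa"
        write_fasta(queries, qf)
        write_fasta(subjects, sf)
        subprocess.run(
            ["makeblastdb", "-in", str(sf), "-dbtype", dbtype],
            check=True,
            capture_output=True,
        )
        res = subprocess.run(
            [
                tool, "-query", str(qf), "-db", str(sf),
                "-evalue", str(cutoff), "-outfmt", "6",
            ],
            check=True,
            capture_output=True,
            text=True,
        )
    hits = []
    for line in res.stdout.splitlines():
        f = line.split("\t")
        hits.append(
            Hit(
                query_id=f[0],
                subject_id=f[1],
                bitscore=float(f[11]),
                evalue=max(float(f[10]), 1e-300),
                query_span=(int(f[6]) - 1, int(f[7])),
                subject_span=(int(f[8]) - 1, int(f[9])),
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return hits


def blastp_search(queries: dict[str, str], proteins: dict[str, str], cutoff: float = 1.0) -> list[Hit]:
    """Protein vs protein database via blastp (tabular output)."""
    return _run_blast("blastp", queries, proteins, "prot", cutoff)


def tblastn_search(queries: dict[str, str], dna: dict[str, str], cutoff: float = 1.0) -> list[Hit]:
    """Protein vs translated DNA database via tblastn."""
    return _run_blast("tblastn", queries, dna, "nucl", cutoff)


def write_hits_tsv(hits: list[Hit], path: str | Path) -> None:
    """12-column tab-separated records, compatible with tabular BLAST output.

    Identity/mismatch/gap columns are not tracked by the built-in engine and
    are written as 0; spans are converted to 1-based inclusive.
    """
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.query_span
            ss, se = h.subject_span
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0\t0\t0\t0\t"
                f"{qs + 1}\t{qe}\t{ss + 1}\t{se}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def read_hits_tsv(path: str | Path) -> list[Hit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != 12:
                raise ValueError("expected 12 tab-separated columns")
            hits.append(
                Hit(
                    query_id=f[0],
                    subject_id=f[1],
                    bitscore=float(f[11]),
                    evalue=float(f[10]),
                    query_span=(int(f[6]) - 1, int(f[7])),
                    subject_span=(int(f[8]) - 1, int(f[9])),
                )
            )
    return hits
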