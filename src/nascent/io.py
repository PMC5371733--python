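"""File formats: bedGraph, GTF, BED6, FASTA, JASPAR PFM, TSV tables.

Conventions: BED and bedGraph are 0-based half-open (native); GTF is 1-based
closed on disk and converted to 0-based half-open on read/write. All in-memory
coordinates in this package are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tracks import StrandedCoverageTrack, n_bins

# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: StrandedCoverageTrack, path_plus, path_minus) -> None:
    """Write one bedGraph per strand; zero bins are omitted."""
    for strand, path in ((("+"), path_plus), (("-"), path_minus)):
        with open(path, "w") as fh:
            for chrom, length in track.genome.items():
                vec = track.data[(chrom, strand)]
                bs = track.bin_size
                nz = np.nonzero(vec)[0]
                for b in nz:
                    end = min((b + 1) * bs, length)
                    val = vec[b]
                    sval = f"{int(val)}" if float(val).is_integer() else f"{val:.6g}"
                    fh.write(f"{chrom}\t{b * bs}\t{end}\t{sval}\n")


def read_bedgraph(path_plus, path_minus, genome: dict, bin_size: int = 200,
                  sample_id: str = "") -> StrandedCoverageTrack:
    track = StrandedCoverageTrack(bin_size=bin_size, genome=genome,
                                  sample_id=sample_id)
    for strand, path in (("+", path_plus), ("-", path_minus)):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"bedGraph not found: {path}")
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"],
                         comment="t")  # skips optional "track ..." header lines
        for row in df.itertuples(index=False):
            vec = track.data[(row.chrom, strand)]
            b0 = int(row.start) // bin_size
            b1 = n_bins(int(row.end), bin_size)
            vec[b0:b1] += float(row.value)
    return track


# ---------------------------------------------------------------------------
# GTF (genes + exons with gene_biotype)


def write_gtf(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    """Write gene and exon records (1-based closed on disk).

    genes: index gene_id, columns chrom/start/end/strand/biotype.
    exons: columns gene_id, transcript_id, chrom, start, end, strand.
    """
    with open(path, "w") as fh:
        for gid, g in genes.iterrows():
            attrs = (f'gene_id "{gid}"; gene_biotype "{g["biotype"]}"; '
                     f'transcript_type "{g["biotype"]}";')
            fh.write(f'{g["chrom"]}\tnascent\tgene\t{g["start"] + 1}\t{g["end"]}\t'
                     f'.\t{g["strand"]}\t.\t{attrs}\n')
            for _, e in exons[exons["gene_id"] == gid].iterrows():
                eattrs = (f'gene_id "{gid}"; transcript_id "{e["transcript_id"]}"; '
                          f'gene_biotype "{g["biotype"]}"; '
                          f'transcript_type "{g["biotype"]}";')
                fh.write(f'{e["chrom"]}\tnascent\texon\t{e["start"] + 1}\t{e["end"]}\t'
                         f'.\t{e["strand"]}\t.\t{eattrs}\n')


def _parse_gtf_attrs(s: str) -> dict:
    out = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read gene and exon records into (genes, exons) frames, 0-based half-open."""
    gene_rows, exon_rows = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, ftype, start, end, _, strand, _, attr_s = f[:9]
            attrs = _parse_gtf_attrs(attr_s)
            biotype = attrs.get("gene_biotype", attrs.get("transcript_type", ""))
            rec = dict(chrom=chrom, start=int(start) - 1, end=int(end),
                       strand=strand, biotype=biotype,
                       gene_id=attrs.get("gene_id", ""))
            if ftype == "gene":
                gene_rows.append(rec)
            elif ftype == "exon":
                rec["transcript_id"] = attrs.get("transcript_id", "")
                exon_rows.append(rec)
    genes = pd.DataFrame(gene_rows)
    if len(genes):
        genes = genes.set_index("gene_id")
    exons = pd.DataFrame(exon_rows,
                         columns=["chrom", "start", "end", "strand", "biotype",
                                  "gene_id", "transcript_id"])
    return genes, exons


# ---------------------------------------------------------------------------
# BED6


def write_bed(df: pd.DataFrame, path) -> None:
    """BED6 from a frame with chrom/start/end (+ optional name/score/strand)."""
    with open(path, "w") as fh:
        for idx, r in df.iterrows():
            name = r.get("name", idx)
            score = r.get("score", 0)
            strand = r.get("strand", ".")
            fh.write(f'{r["chrom"]}\t{r["start"]}\t{r["end"]}\t{name}\t{score}\t{strand}\n')


def read_bed(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    return df


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# JASPAR PFMs


def read_pfms(path) -> dict:
    """Read JASPAR-format position frequency matrices -> {id: 4xW count array}."""
    with open(path) as fh:
        mlist = motifs.parse(fh, "jaspar")
    out = {}
    for m in mlist:
        mat = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out[m.matrix_id or m.name] = mat
    return out


def write_pfms(pfms: dict, path) -> None:
    with open(path, "w") as fh:
        for pid, mat in pfms.items():
            fh.write(f">{pid} {pid}\n")
            for base, row in zip("ACGT", np.asarray(mat)):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# TSV tables


def write_count_matrix(counts: pd.DataFrame, lengths: pd.Series, path) -> None:
    out = counts.copy()
    out.insert(0, "length_bp", lengths.reindex(counts.index))
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_count_matrix(path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    lengths = df.pop("length_bp")
    return df, lengths


def write_spikein_table(spike: pd.DataFrame, path) -> None:
    spike.to_csv(path, sep="\t", index=True, index_label="id")


def read_spikein_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
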