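"""Sequence ingestion, observation encoding, and results I/O.

Coordinates are 0-based half-open everywhere (BedGraph convention).  Input
pairs are either two aligned haploid FASTA files or a single diploid FASTA
with IUPAC ambiguity codes for heterozygous sites; gaps and N are missing
data in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .hmm import ObservedSequence
from .maps import BinnedMap, RecombinationMap

__all__ = [
    "SamplePair",
    "read_fasta",
    "write_fasta",
    "load_pair",
    "load_diploid",
    "encode_observations",
    "write_bedgraph",
    "read_bedgraph",
    "write_site_map",
    "read_site_map",
    "read_config",
]

_ACGT = b"ACGT"
_IUPAC_HET = b"RYSWKM"       # two-allele ambiguity codes
_MISSING_CHARS = b"N-BDHV"   # unknown / gap / 3+-allele ambiguity

# lookup tables over the byte range: 0 hom-base, 1 het, 2 missing, 255 invalid
_LUT_HAPLOID = np.full(256, 255, dtype=np.uint8)
for _c in _ACGT:
    _LUT_HAPLOID[_c] = 0
    _LUT_HAPLOID[ord(chr(_c).lower())] = 0
for _c in b"N-":
    _LUT_HAPLOID[_c] = 2
_LUT_HAPLOID[ord("n")] = 2

_LUT_DIPLOID = np.full(256, 255, dtype=np.uint8)
for _c in _ACGT:
    _LUT_DIPLOID[_c] = 0
    _LUT_DIPLOID[ord(chr(_c).lower())] = 0
for _c in _IUPAC_HET:
    _LUT_DIPLOID[_c] = 1
    _LUT_DIPLOID[ord(chr(_c).lower())] = 1
for _c in _MISSING_CHARS:
    _LUT_DIPLOID[_c] = 2
    _LUT_DIPLOID[ord(chr(_c).lower())] = 2


@dataclass
class SamplePair:
    """Aligned input genomes: either two haploids or one diploid.

    ``contigs`` is a list of (name, seq_a, seq_b) byte strings; in diploid
    mode ``seq_b`` is None.
    """

    contigs: list
    diploid: bool = False


def read_fasta(path) -> dict:
    """name -> uppercase sequence bytes."""
    from Bio import SeqIO

    out = {rec.id: str(rec.seq).upper().encode()
           for rec in SeqIO.parse(str(path), "fasta")}
    if not out:
        raise InvalidInputError(f"no FASTA records in {path}")
    return out


def write_fasta(path, records, width: int = 80):
    """Write records; line wrapping is Biopython's (``width`` ignored)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq.decode() if isinstance(seq, bytes) else seq),
                      id=name, description="")
            for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def load_pair(path_a, path_b) -> SamplePair:
    """Two aligned haploid FASTAs; contigs matched by name (order of the
    first file)."""
    a = read_fasta(path_a)
    b = read_fasta(path_b)
    contigs = []
    for name, seq_a in a.items():
        if name not in b:
            raise InvalidInputError(f"contig {name} absent from {path_b}")
        seq_b = b[name]
        if len(seq_a) != len(seq_b):
            raise InvalidInputError(
                f"length mismatch on contig {name}: "
                f"{len(seq_a)} vs {len(seq_b)}")
        contigs.append((name, seq_a, seq_b))
    return SamplePair(contigs=contigs, diploid=False)


def load_diploid(path) -> SamplePair:
    """A single diploid FASTA with IUPAC heterozygote codes."""
    recs = read_fasta(path)
    return SamplePair(contigs=[(n, s, None) for n, s in recs.items()],
                      diploid=True)


def _encode_contig(name, seq_a, seq_b, diploid):
    if diploid:
        arr = np.frombuffer(seq_a, dtype=np.uint8)
        codes = _LUT_DIPLOID[arr]
        bad = np.flatnonzero(codes == 255)
        if bad.size:
            raise InvalidInputError(
                f"invalid character {chr(arr[bad[0]])!r} at position "
                f"{bad[0]} of contig {name}")
        return codes
    a = np.frombuffer(seq_a, dtype=np.uint8)
    b = np.frombuffer(seq_b, dtype=np.uint8)
    ca = _LUT_HAPLOID[a]
    cb = _LUT_HAPLOID[b]
    for arr, cc in ((a, ca), (b, cb)):
        bad = np.flatnonzero(cc == 255)
        if bad.size:
            raise InvalidInputError(
                f"invalid character {chr(arr[bad[0]])!r} at position "
                f"{bad[0]} of contig {name}")
    # case-insensitive base comparison
    au = np.where((a >= 97), a - 32, a)
    bu = np.where((b >= 97), b - 32, b)
    codes = np.where(au == bu, 0, 1).astype(np.uint8)
    codes[(ca == 2) | (cb == 2)] = 2
    return codes


def encode_observations(pair: SamplePair) -> ObservedSequence:
    """Per-site codes: 0 both bases equal, 1 different (or IUPAC het),
    2 missing (gap/N/multi-base ambiguity)."""
    parts = []
    contigs = []
    pos = 0
    for name, seq_a, seq_b in pair.contigs:
        codes = _encode_contig(name, seq_a, seq_b, pair.diploid)
        parts.append(codes)
        contigs.append((name, pos, pos + len(codes)))
        pos += len(codes)
    return ObservedSequence(np.concatenate(parts) if parts
                            else np.empty(0, dtype=np.uint8), contigs)


# ---------------------------------------------------------------------------
# maps on disk
# ---------------------------------------------------------------------------

def write_bedgraph(path, binned: BinnedMap):
    """4-column BedGraph; masked windows carry value ``nan``."""
    binned.to_frame().to_csv(path, sep="\t", header=False, index=False,
                             float_format="%.10g")


def read_bedgraph(path) -> BinnedMap:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    if df.empty:
        raise InvalidInputError(f"empty BedGraph {path}")
    width = int((df["end"] - df["start"]).max())
    mask = df["value"].isna().to_numpy()
    return BinnedMap(chroms=df["chrom"].to_numpy(),
                     starts=df["start"].to_numpy(dtype=int),
                     ends=df["end"].to_numpy(dtype=int),
                     values=df["value"].to_numpy(dtype=float),
                     missing_frac=np.full(len(df), np.nan),
                     mask=mask, width=width)


def write_site_map(path, rmap: RecombinationMap):
    """Per-site map: position, rho, missing flag (tab-separated)."""
    df = pd.DataFrame({"pos": np.arange(len(rmap)), "rho": rmap.rho,
                       "missing": rmap.missing.astype(int)})
    df.to_csv(path, sep="\t", header=False, index=False,
              float_format="%.8g")


def read_site_map(path) -> RecombinationMap:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["pos", "rho", "missing"])
    return RecombinationMap(rho=df["rho"].to_numpy(dtype=float),
                            missing=df["missing"].to_numpy(dtype=bool),
                            contigs=[("seq", 0, len(df))])


def read_config(path) -> dict:
    """Flat key=value configuration file; '#' starts a comment."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected key=value")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out
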