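"""File-format boundaries: FASTA, GFF3, GMT, tab-separated tables.

Hairpin precursors are read from FASTA; mature annotations come either
from a sidecar GFF3 (coordinates 1-based inclusive on the hairpin, per the
GFF3 convention, converted to 0-based half-open internally) or from a
mature FASTA whose sequences are located on the hairpins by exact
substring. All sequences are uppercased and U-normalised to T on ingestion.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from gseapy.parser import read_gmt as _read_gmt

from .matcher import MatureAnnotation, Precursor, assign_arm


class IOFormatError(ValueError):
    pass


def _norm(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


def read_precursor_fasta(path) -> dict[str, dict]:
    """Hairpin FASTA -> id -> {sequence, chrom, start, end, strand}.

    Genomic location may be encoded in the description as
    ``chrom:start-end(strand)`` (0-based half-open); records without it get
    placeholder coordinates on their own pseudo-chromosome, which disables
    genomic clustering but nothing else.
    """
    out = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        loc = None
        for token in rec.description.split():
            if ":" in token and "-" in token and token.endswith(")"):
                try:
                    chrom, rest = token.split(":", 1)
                    span, strand = rest[:-1].rsplit("(", 1)
                    start, end = (int(x) for x in span.split("-"))
                    loc = (chrom, start, end, strand)
                except ValueError:
                    continue
        if loc is None:
            loc = (f"unplaced_{i}", 0, len(rec.seq), "+")
        out[rec.id] = {
            "sequence": _norm(rec.seq),
            "chrom": loc[0],
            "start": loc[1],
            "end": loc[2],
            "strand": loc[3],
        }
    if not out:
        raise IOFormatError(f"no FASTA records in {path}")
    return out


def load_precursors(
    hairpin_fasta,
    mature_gff3=None,
    mature_fasta=None,
    family_map: pd.DataFrame | None = None,
) -> list[Precursor]:
    """Assemble annotated precursors from a hairpin FASTA plus matures.

    Exactly one of ``mature_gff3`` (mature coordinates on the hairpin) or
    ``mature_fasta`` (mature sequences located by exact substring; more
    than one occurrence within a hairpin is an error) must be given. A
    family map (two columns: family_id, mature_id) annotates families.
    """
    if (mature_gff3 is None) == (mature_fasta is None):
        raise IOFormatError("provide exactly one of mature_gff3 or mature_fasta")
    hairpins = read_precursor_fasta(hairpin_fasta)
    fam: dict[str, str] = {}
    if family_map is not None:
        for fid, mid in family_map.iloc[:, :2].itertuples(index=False):
            fam[str(mid)] = str(fid)

    matures_by_hairpin: dict[str, list[tuple[str, int, int, str | None]]] = {}
    if mature_gff3 is not None:
        for seqid, mid, start0, end0, arm in _parse_mature_gff3(mature_gff3):
            if seqid not in hairpins:
                raise IOFormatError(f"GFF3 seqid {seqid!r} not in hairpin FASTA")
            matures_by_hairpin.setdefault(seqid, []).append((mid, start0, end0, arm))
    else:
        for rec in SeqIO.parse(str(mature_fasta), "fasta"):
            mseq = _norm(rec.seq)
            placed = False
            for hid, h in hairpins.items():
                first = h["sequence"].find(mseq)
                if first == -1:
                    continue
                if h["sequence"].find(mseq, first + 1) != -1:
                    raise IOFormatError(
                        f"mature {rec.id} occurs more than once in hairpin {hid}"
                    )
                matures_by_hairpin.setdefault(hid, []).append(
                    (rec.id, first, first + len(mseq), None)
                )
                placed = True
            if not placed:
                raise IOFormatError(f"mature {rec.id} not found in any hairpin")

    precursors = []
    for hid, h in hairpins.items():
        entries = matures_by_hairpin.get(hid)
        if not entries:
            continue
        anns = []
        for mid, s, e, arm in sorted(entries, key=lambda t: t[1]):
            anns.append(
                MatureAnnotation(
                    id=mid,
                    arm=arm or assign_arm(s, e, len(h["sequence"])),
                    p_start=s,
                    p_end=e,
                    family_id=fam.get(mid),
                )
            )
        precursors.append(
            Precursor(
                id=hid,
                sequence=h["sequence"],
                chrom=h["chrom"],
                start=h["start"],
                end=h["end"],
                strand=h["strand"],
                matures=tuple(anns),
            )
        )
    if not precursors:
        raise IOFormatError("no hairpin carries a mature annotation")
    return precursors


def _parse_mature_gff3(path):
    """Yield (seqid, mature_id, start0, end0, arm) from a mature GFF3."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    for feat in db.all_features():
        if feat.featuretype not in ("miRNA", "mature_miRNA"):
            continue
        mid = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        arm = feat.attributes.get("arm", [None])[0]
        yield feat.seqid, mid, feat.start - 1, feat.end, arm


def write_precursor_fasta(precursors: list[Precursor], path) -> None:
    with open(path, "w") as fh:
        for p in precursors:
            fh.write(f">{p.id} {p.chrom}:{p.start}-{p.end}({p.strand})\n{p.sequence}\n")


def write_mature_gff3(precursors: list[Precursor], path) -> None:
    """Sidecar GFF3 of mature coordinates on the hairpins (1-based incl.)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in precursors:
            for m in p.matures:
                attrs = f"ID={m.id};Name={m.id};arm={m.arm}"
                if m.family_id:
                    attrs += f";family={m.family_id}"
                fh.write(
                    f"{p.id}\t.\tmiRNA\t{m.p_start + 1}\t{m.p_end}\t.\t+\t.\t{attrs}\n"
                )


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets -> pathway id -> member gene set."""
    return {name: set(genes) for name, genes in _read_gmt(str(path)).items()}


def read_family_map(path) -> pd.DataFrame:
    """Two-column (family_id, mature_id) table, miRBase family style."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise IOFormatError("family map needs two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["family_id", "mature_id"]
    return df.drop_duplicates().reset_index(drop=True)
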