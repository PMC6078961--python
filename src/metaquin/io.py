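"""File formats: FASTA, mixture/pair CSV, annotation CSV, counts CSV.

The mixture CSV dialect is fixed (header
``id,length,gc,point,concentration_amol_per_ul``, UTF-8, LF line endings,
'.' decimal); floats are written with shortest-round-trip ``repr`` so that
write -> parse -> write is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import SequinRecord
from .mixtures import MixPairSpec, MixtureEntry, MixtureSpec

MIXTURE_HEADER = "id,length,gc,point,concentration_amol_per_ul"
PAIR_HEADER = MIXTURE_HEADER + ",concentration_b,expected_lfc,role"


class ParseError(ValueError):
    pass


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_sequin_fasta(sequins: list[SequinRecord], path) -> None:
    write_fasta({s.id: s.sequence for s in sequins}, path)


def write_sequin_annotation(sequins: list[SequinRecord], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("id,length,gc,source_id,start,end\n")
        for s in sequins:
            fh.write(
                f"{s.id},{s.length},{s.gc!r},{s.source_id},"
                f"{s.source_window[0]},{s.source_window[1]}\n"
            )


def read_sequin_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _fmt(value: float) -> str:
    return repr(float(value))


def write_mixture_csv(spec: MixtureSpec, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(MIXTURE_HEADER + "\n")
        for e in spec.entries:
            fh.write(
                f"{e.sequin_id},{e.length},{_fmt(e.gc)},{e.point_index},"
                f"{_fmt(e.concentration)}\n"
            )


def parse_mixture_csv(path) -> MixtureSpec:
    path = Path(path)
    entries: list[MixtureEntry] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != MIXTURE_HEADER:
            raise ParseError(f"{path}:1: malformed header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields")
            sid, length, gc, point, conc = parts
            if sid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate id {sid!r}")
            seen.add(sid)
            try:
                concentration = float(conc)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: bad concentration {conc!r}"
                ) from None
            if concentration <= 0:
                raise ParseError(
                    f"{path}:{lineno}: non-positive concentration {conc}"
                )
            entries.append(
                MixtureEntry(
                    sequin_id=sid,
                    concentration=concentration,
                    point_index=int(point),
                    length=int(length),
                    gc=float(gc),
                )
            )
    return MixtureSpec(name=path.stem, entries=entries)


def write_pair_csv(pair: MixPairSpec, path) -> None:
    import math

    conc_b = pair.mix_b.concentrations
    with open(path, "w", newline="\n") as fh:
        fh.write(PAIR_HEADER + "\n")
        for e in pair.mix_a.entries:
            cb = conc_b[e.sequin_id]
            lfc = math.log2(cb / e.concentration)
            fh.write(
                f"{e.sequin_id},{e.length},{_fmt(e.gc)},{e.point_index},"
                f"{_fmt(e.concentration)},{_fmt(cb)},{_fmt(lfc)},"
                f"{pair.roles[e.sequin_id]}\n"
            )


def parse_pair_csv(path) -> MixPairSpec:
    path = Path(path)
    entries_a: list[MixtureEntry] = []
    entries_b: list[MixtureEntry] = []
    roles: dict[str, str] = {}
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != PAIR_HEADER:
            raise ParseError(f"{path}:1: malformed header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 8:
                raise ParseError(f"{path}:{lineno}: expected 8 fields")
            sid, length, gc, point, ca, cb, _lfc, role = parts
            if sid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate id {sid!r}")
            seen.add(sid)
            if float(ca) <= 0 or float(cb) <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive concentration")
            entries_a.append(
                MixtureEntry(sid, float(ca), int(point), int(length), float(gc))
            )
            entries_b.append(
                MixtureEntry(sid, float(cb), int(point), int(length), float(gc))
            )
            roles[sid] = role
    return MixPairSpec(
        mix_a=MixtureSpec(name=path.stem + "_A", entries=entries_a),
        mix_b=MixtureSpec(name=path.stem + "_B", entries=entries_b),
        roles=roles,
    )


def read_community_yaml(path) -> tuple[list[tuple[str, str | int, float]],
                                       tuple[str, float] | None]:
    """Community spec YAML: members plus an optional spike mode.

    Layout::

        members:
          - {id: sp1, length: 100000, mass: 2.0}   # or sequence: ACGT...
        spike: {mode: fractional, value: 0.05}     # or {mode: fixed, ...}
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "members" not in doc:
        raise ParseError(f"{path}: expected a mapping with a 'members' list")
    members: list[tuple[str, str | int, float]] = []
    for i, m in enumerate(doc["members"]):
        try:
            seq_or_len = m["sequence"] if "sequence" in m else int(m["length"])
            members.append((str(m["id"]), seq_or_len, float(m["mass"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: bad member #{i + 1}: {exc}") from None
    spike = None
    if "spike" in doc and doc["spike"] is not None:
        s = doc["spike"]
        if s.get("mode") not in ("fractional", "fixed"):
            raise ParseError(f"{path}: spike mode must be fractional or fixed")
        spike = (s["mode"], float(s["value"]))
    return members, spike


def read_counts_csv(path) -> pd.DataFrame:
    """Count matrix CSV: features as rows, header row of sample ids."""
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise ParseError(f"duplicate feature ids: {', '.join(map(str, dups))}")
    return df


def write_counts_csv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, lineterminator="\n")
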