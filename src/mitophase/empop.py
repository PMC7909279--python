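"""EMPOP-dialect haplotype tables, bi-allelic site universes, and allele-count I/O.

Forensic mtDNA profiles are conventionally exchanged as lists of differences
from the revised Cambridge Reference Sequence (rCRS): a sample identifier
followed by variant tokens such as ``263G`` (substitution), ``315.1C``
(insertion) or ``249DEL`` (deletion), with 1-based rCRS coordinates
throughout.  This module parses and writes that dialect, collapses a parsed
database onto the ordered bi-allelic SNP universe the phasing engine
requires (indels and multi-allelic positions are dropped), and round-trips
the per-site reference/alternative read-count tables that carry the
quantitative mixture signal.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

RCRS_LENGTH = 16_569

# Genotype classes of a mixed sample at one bi-allelic site.
HE = "He"        # both alleles observed
HOR = "HoR"      # reference allele only
HOA = "HoA"      # alternative allele only
MISSING = "missing"  # zero read depth

_BASES = "ACGT"

_SUB_RE = re.compile(r"^(\d+)([ACGTacgt])$")
_INS_RE = re.compile(r"^(\d+)\.(\d+)([ACGTacgt])$")
_DEL_RE = re.compile(r"^(\d+)(?:DEL|del|Del|-)$")


class EmpopParseError(ValueError):
    """Raised for malformed EMPOP records; names the offending line and token."""


class CountTableError(ValueError):
    """Raised for malformed allele-count tables."""


@dataclass(frozen=True)
class VariantToken:
    """One rCRS-relative difference: substitution, insertion or deletion."""

    position: int
    kind: str  # "substitution" | "insertion" | "deletion"
    base: str | None = None
    insertion_index: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.position <= RCRS_LENGTH:
            raise EmpopParseError(
                f"position {self.position} outside rCRS range 1..{RCRS_LENGTH}"
            )
        if self.kind == "substitution" and (self.base not in _BASES):
            raise EmpopParseError(f"substitution at {self.position} needs a base in {_BASES}")
        if self.kind == "insertion":
            if self.base not in _BASES or not self.insertion_index or self.insertion_index < 1:
                raise EmpopParseError(f"insertion at {self.position} needs index >= 1 and a base")
        if self.kind == "deletion" and self.base is not None:
            raise EmpopParseError(f"deletion at {self.position} carries no base")

    def __str__(self) -> str:
        if self.kind == "substitution":
            return f"{self.position}{self.base}"
        if self.kind == "insertion":
            return f"{self.position}.{self.insertion_index}{self.base}"
        return f"{self.position}DEL"


@dataclass(frozen=True)
class SiteLocus:
    """A bi-allelic SNP site: 1-based rCRS position plus its two alleles."""

    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"site {self.position}: ref and alt alleles must differ")


@dataclass
class Haplotype:
    """A sample's binary allele vector over an ordered SiteLocus list.

    ``alleles[j] == 1`` means the sample carries the alternative allele of
    site ``j``; 0 means the reference allele.
    """

    sample_id: str
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 1:
            raise ValueError("allele vector must be one-dimensional")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele vector entries must be 0 or 1")

    def __len__(self) -> int:
        return self.alleles.size


@dataclass
class SiteCountTable:
    """Per-site reference/alternative read counts for one mixed sample."""

    loci: list[SiteLocus]
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        if not (len(self.loci) == self.ref_counts.size == self.alt_counts.size):
            raise CountTableError("loci, ref_counts and alt_counts must have equal length")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise CountTableError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    def __len__(self) -> int:
        return len(self.loci)


def reference_base(position: int) -> str:
    """Deterministic stand-in reference base for an rCRS position.

    The phasing model only needs a consistent ref/alt labelling per site, not
    the true rCRS nucleotide; this synthetic assignment is used whenever no
    reference FASTA is supplied.
    """
    return _BASES[position % 4]


def load_reference_fasta(path) -> str:
    """Read a single-record reference FASTA (e.g. the rCRS) into a string."""
    seq: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                continue
            seq.append(line.strip().upper())
    return "".join(seq)


def _parse_token(token: str, line_no: int) -> VariantToken:
    if m := _SUB_RE.match(token):
        pos, base = int(m.group(1)), m.group(2).upper()
        if not 1 <= pos <= RCRS_LENGTH:
            raise EmpopParseError(f"line {line_no}: token {token!r}: position out of range")
        return VariantToken(pos, "substitution", base)
    if m := _INS_RE.match(token):
        pos, idx, base = int(m.group(1)), int(m.group(2)), m.group(3).upper()
        if not 1 <= pos <= RCRS_LENGTH:
            raise EmpopParseError(f"line {line_no}: token {token!r}: position out of range")
        return VariantToken(pos, "insertion", base, insertion_index=idx)
    if m := _DEL_RE.match(token):
        pos = int(m.group(1))
        if not 1 <= pos <= RCRS_LENGTH:
            raise EmpopParseError(f"line {line_no}: token {token!r}: position out of range")
        return VariantToken(pos, "deletion")
    raise EmpopParseError(f"line {line_no}: unrecognized variant token {token!r}")


def parse_empop(stream: TextIO | str) -> list[tuple[str, list[VariantToken]]]:
    """Parse an EMPOP-dialect table: one sample per line, ID then variant tokens.

    Lines are tab-separated into an ID column and a token column; tokens
    within the token column are whitespace-separated.  A sample identical to
    the reference carries an empty token list.  Blank lines and ``#``
    comments are skipped.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[tuple[str, list[VariantToken]]] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t", 1)
        sample_id = parts[0].strip()
        if not sample_id:
            raise EmpopParseError(f"line {line_no}: empty sample ID")
        token_field = parts[1] if len(parts) > 1 else ""
        tokens = [_parse_token(t, line_no) for t in token_field.split()]
        records.append((sample_id, tokens))
    return records


def serialize_empop(records: Iterable[tuple[str, Sequence[VariantToken]]]) -> str:
    """Inverse of :func:`parse_empop` on well-formed records."""
    lines = []
    for sample_id, tokens in records:
        lines.append(sample_id + "\t" + " ".join(str(t) for t in tokens))
    return "\n".join(lines) + "\n"


def read_empop(path) -> list[tuple[str, list[VariantToken]]]:
    with open(path) as fh:
        return parse_empop(fh)


def write_empop(records, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize_empop(records))


def build_site_universe(
    records: Sequence[tuple[str, Sequence[VariantToken]]],
    reference: str | None = None,
) -> tuple[list[SiteLocus], list[Haplotype]]:
    """Collapse parsed records onto the engine's ordered bi-allelic SNP universe.

    Insertions and deletions are dropped, as is any position at which more
    than one distinct alternative base is observed across the whole input
    (a multi-allelic site, counting the reference base as one allele).  The
    surviving positions, sorted, define the site list; each sample becomes a
    binary haplotype with 1 wherever it carries a site's alternative allele.

    Because the phasing engine assumes a single shared bi-allelic coding,
    callers should concatenate database, mixture-source and panel records
    before calling so that all components share one universe.
    """
    ref_at = (lambda p: reference[p - 1]) if reference else reference_base

    alt_bases: dict[int, set[str]] = {}
    for _, tokens in records:
        for tok in tokens:
            if tok.kind != "substitution":
                continue
            if tok.base == ref_at(tok.position):
                continue  # no-op "variant" equal to the reference base
            alt_bases.setdefault(tok.position, set()).add(tok.base)

    positions = sorted(p for p, bases in alt_bases.items() if len(bases) == 1)
    loci = [SiteLocus(p, ref_at(p), next(iter(alt_bases[p]))) for p in positions]
    index = {p: j for j, p in enumerate(positions)}

    haplotypes = []
    for sample_id, tokens in records:
        vec = np.zeros(len(loci), dtype=np.int8)
        for tok in tokens:
            if tok.kind != "substitution":
                continue
            j = index.get(tok.position)
            if j is not None and tok.base == loci[j].alt_allele:
                vec[j] = 1
        haplotypes.append(Haplotype(sample_id, vec))
    return loci, haplotypes


def haplotype_to_tokens(hap: Haplotype, loci: Sequence[SiteLocus]) -> list[VariantToken]:
    """Express a binary haplotype as EMPOP substitution tokens (alt sites only)."""
    if len(hap) != len(loci):
        raise ValueError("haplotype and site list lengths differ")
    return [
        VariantToken(loc.position, "substitution", loc.alt_allele)
        for loc, a in zip(loci, hap.alleles)
        if a == 1
    ]


def classify_sites(counts: SiteCountTable) -> list[str]:
    """Label every site He / HoR / HoA, or missing at zero depth."""
    labels = []
    for r, a in zip(counts.ref_counts, counts.alt_counts):
        if r == 0 and a == 0:
            labels.append(MISSING)
        elif r > 0 and a > 0:
            labels.append(HE)
        elif a == 0:
            labels.append(HOR)
        else:
            labels.append(HOA)
    return labels


_COUNT_COLUMNS = ["POS", "REF", "ALT", "REF_COUNT", "ALT_COUNT"]


def write_counts(table: SiteCountTable, path_or_buf) -> None:
    """Write a SiteCountTable as TSV with columns POS REF ALT REF_COUNT ALT_COUNT."""
    df = pd.DataFrame(
        {
            "POS": [loc.position for loc in table.loci],
            "REF": [loc.ref_allele for loc in table.loci],
            "ALT": [loc.alt_allele for loc in table.loci],
            "REF_COUNT": table.ref_counts,
            "ALT_COUNT": table.alt_counts,
        }
    )
    df.to_csv(path_or_buf, sep="\t", index=False)


def read_counts(path_or_buf) -> SiteCountTable:
    """Read a SiteCountTable TSV written by :func:`write_counts`."""
    try:
        df = pd.read_csv(path_or_buf, sep="\t", dtype={"REF": str, "ALT": str})
    except Exception as exc:  # noqa: BLE001 - normalize to a format error
        raise CountTableError(f"unreadable count table: {exc}") from exc
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"count table missing columns: {missing}")
    for col in ("POS", "REF_COUNT", "ALT_COUNT"):
        if len(df) and not pd.api.types.is_integer_dtype(df[col]):
            raise CountTableError(f"column {col} must be integer")
    loci = [
        SiteLocus(int(p), r, a) for p, r, a in zip(df["POS"], df["REF"], df["ALT"])
    ]
    return SiteCountTable(loci, df["REF_COUNT"].to_numpy(), df["ALT_COUNT"].to_numpy())
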