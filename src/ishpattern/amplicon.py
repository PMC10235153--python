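"""Exact-match in-silico PCR for probe primer validation.

Given a primer pair and a template, the predicted amplicon is the unique
plus-strand slice that begins with the forward primer and ends with the
reverse complement of the reverse primer (primers included in the length).
Both orientations of the pair are searched; zero products is a
:class:`NoAmpliconError`, more than one an :class:`AmbiguousPrimingError`
(a specificity failure, not a choice to be made silently).

Matching is exact — the probe primers were designed against the cited
assemblies, so no mismatch or degenerate-base tolerance is applied.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "PrimerPair",
    "AmpliconHit",
    "NoAmpliconError",
    "AmbiguousPrimingError",
    "revcomp",
    "find_amplicon",
    "check_primer_table",
    "read_primer_table",
    "load_probe_primer_table",
    "read_templates",
    "synthetic_template",
]

_DNA = set("ACGTN")


class NoAmpliconError(ValueError):
    """The primer pair yields no product on the template."""


class AmbiguousPrimingError(ValueError):
    """The primer pair yields more than one product on the template."""

    def __init__(self, hits: list["AmpliconHit"]):
        self.hits = hits
        spans = ", ".join(f"[{h.start},{h.end}) {h.strand_of_forward}" for h in hits)
        super().__init__(f"{len(hits)} products found: {spans}")


@dataclass(frozen=True)
class PrimerPair:
    """One probe primer pair, 5'->3' on each strand, with its expected product size."""

    gene: str
    species: str
    accession: str
    forward: str
    reverse: str
    expected_size: int

    def __post_init__(self) -> None:
        for name in ("forward", "reverse"):
            seq = getattr(self, name).upper()
            object.__setattr__(self, name, seq)
            bad = set(seq) - set("ACGT")
            if bad or not seq:
                raise ValueError(
                    f"{name} primer of {self.gene} contains invalid characters {sorted(bad)}"
                    if bad
                    else f"{name} primer of {self.gene} is empty"
                )
        if self.expected_size < max(len(self.forward), len(self.reverse)):
            raise ValueError(
                f"expected_size {self.expected_size} is shorter than a primer"
            )


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted product, 0-based half-open on the template plus strand."""

    template_id: str
    start: int
    end: int
    strand_of_forward: str  # "plus" | "minus"

    @property
    def length(self) -> int:
        return self.end - self.start


def revcomp(seq: str) -> str:
    """Reverse complement over the {A, C, G, T, N} alphabet (N -> N)."""
    seq = seq.upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return str(Seq(seq).reverse_complement())


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) match start positions."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _plus_strand_products(template: str, fwd: str, rev: str) -> list[tuple[int, int]]:
    """(start, end) spans with fwd on the plus strand and rev priming downstream."""
    rc_rev = revcomp(rev)
    rev_sites = _find_all(template, rc_rev)
    spans = []
    for i in _find_all(template, fwd):
        for j in rev_sites:
            if j >= i + len(fwd):
                spans.append((i, j + len(rev)))
    return spans


def find_amplicon(template: str, pair: PrimerPair, template_id: str = "template") -> AmpliconHit:
    """Predict the unique product of ``pair`` on ``template`` (exact matching).

    Both orientations are searched: the forward primer on the plus strand
    (product read left to right) and on the minus strand (the pair amplifies
    the reverse-complemented locus).  Coordinates are always reported on the
    template plus strand.
    """
    template = template.upper()
    bad = set(template) - _DNA
    if bad:
        raise ValueError(f"template contains invalid characters: {sorted(bad)}")

    hits = [
        AmpliconHit(template_id, s, e, "plus")
        for s, e in _plus_strand_products(template, pair.forward, pair.reverse)
    ]
    n = len(template)
    rc_template = revcomp(template)
    for s, e in _plus_strand_products(rc_template, pair.forward, pair.reverse):
        hit = AmpliconHit(template_id, n - e, n - s, "minus")
        if not any(h.start == hit.start and h.end == hit.end for h in hits):
            hits.append(hit)

    if not hits:
        raise NoAmpliconError(
            f"no amplicon for {pair.gene} ({pair.species}) on {template_id}"
        )
    if len(hits) > 1:
        raise AmbiguousPrimingError(sorted(hits, key=lambda h: (h.start, h.end)))
    return hits[0]


def check_primer_table(
    pairs: Iterable[PrimerPair], templates: Mapping[str, str]
) -> pd.DataFrame:
    """Validate each pair against its accession's template.

    Returns one row per pair with the computed product length, the expected
    length and a match flag.  A missing template or a priming failure is
    reported in the ``status`` column rather than raised.
    """
    rows = []
    for pair in pairs:
        row = {
            "gene": pair.gene,
            "species": pair.species,
            "accession": pair.accession,
            "expected_size": pair.expected_size,
            "computed_size": pd.NA,
            "match": False,
            "status": "ok",
        }
        template = templates.get(pair.accession)
        if template is None:
            row["status"] = "template unavailable"
        else:
            try:
                hit = find_amplicon(template, pair, template_id=pair.accession)
            except NoAmpliconError:
                row["status"] = "no amplicon"
            except AmbiguousPrimingError as err:
                row["status"] = f"ambiguous priming ({len(err.hits)} products)"
            else:
                row["computed_size"] = hit.length
                row["match"] = hit.length == pair.expected_size
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O and fixtures

def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """Read a primer CSV (gene, species, accession, forward, reverse, expected_size)."""
    frame = pd.read_csv(path)
    required = {"gene", "species", "accession", "forward", "reverse", "expected_size"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"primer table {path} lacks columns: {sorted(missing)}")
    return [
        PrimerPair(
            gene=str(r.gene),
            species=str(r.species),
            accession=str(r.accession),
            forward=str(r.forward),
            reverse=str(r.reverse),
            expected_size=int(r.expected_size),
        )
        for r in frame.itertuples()
    ]


def load_probe_primer_table() -> list[PrimerPair]:
    """The package's shipped table of the ten probe primer pairs."""
    ref = resources.files("ishpattern") / "data" / "probe_primers.csv"
    with resources.as_file(ref) as path:
        return read_primer_table(path)


def read_templates(path: str | Path) -> dict[str, str]:
    """Read FASTA (optionally gzipped) into {record id: sequence}."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as handle:
            records = list(SeqIO.parse(handle, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    return {rec.id: str(rec.seq).upper() for rec in records}


def synthetic_template(
    pair: PrimerPair,
    seed: int = 0,
    flank: int = 60,
    max_attempts: int = 20,
) -> str:
    """Build a SYNTHETIC template carrying exactly one product of the right size.

    This is a stand-in for the cited genomic locus, not its sequence: random
    flanks and a random insert are wrapped around the planted primer sites so
    that the unique product length equals ``pair.expected_size``.  Drawn
    deterministically from ``seed``; regenerated if the random filler happens
    to create a spurious priming site.
    """
    import zlib

    import numpy as np

    insert_len = pair.expected_size - len(pair.forward) - len(pair.reverse)
    if insert_len < 0:
        raise ValueError("expected_size shorter than the two primers combined")
    stream = zlib.crc32(f"{pair.accession}/{pair.gene}/{pair.species}".encode())
    rng = np.random.default_rng(np.random.SeedSequence((stream, seed)))
    bases = np.array(list("ACGT"))
    for _ in range(max_attempts):
        pad5 = "".join(rng.choice(bases, size=flank))
        insert = "".join(rng.choice(bases, size=insert_len))
        pad3 = "".join(rng.choice(bases, size=flank))
        template = pad5 + pair.forward + insert + revcomp(pair.reverse) + pad3
        try:
            hit = find_amplicon(template, pair)
        except (NoAmpliconError, AmbiguousPrimingError):
            continue
        if hit.length == pair.expected_size:
            return template
    raise RuntimeError(
        f"could not build an unambiguous synthetic template for {pair.gene} "
        f"({pair.species}) in {max_attempts} attempts"
    )


def synthetic_template_set(pairs: Iterable[PrimerPair], seed: int = 0) -> dict[str, str]:
    """One SYNTHETIC template per accession, covering every pair's locus.

    Pairs sharing an accession (two genes on one chromosome) are planted on
    the same template, mirroring the real situation of one sequence carrying
    several loci; each pair is verified to yield exactly one product of its
    expected size on its accession's template.
    """
    by_accession: dict[str, list[PrimerPair]] = {}
    for pair in pairs:
        by_accession.setdefault(pair.accession, []).append(pair)
    templates = {
        acc: "".join(synthetic_template(p, seed=seed) for p in group)
        for acc, group in by_accession.items()
    }
    for acc, group in by_accession.items():
        for pair in group:
            hit = find_amplicon(templates[acc], pair, template_id=acc)
            if hit.length != pair.expected_size:
                raise RuntimeError(
                    f"planted template for {acc} gives a {hit.length} bp product "
                    f"for {pair.gene}, expected {pair.expected_size}"
                )
    return templates
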