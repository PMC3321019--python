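"""Normalize tagged protein surface forms to official gene symbols.

Resolution follows a deterministic cascade restricted to the species
detected in the abstract (title, body, MeSH): case-sensitive exact match
over the gene-catalog fields in priority order (official symbol,
synonym, full name, other symbol, locus tag), then case-insensitive,
then the same two passes over rule-based surface variants ("XXX 1" →
"XXX1", "XXX receptor" → "XXXR", strip a trailing general ending such as
"protein"/"gene"/"beta").  The first field with at least one hit
decides; several hits in that field are reported as ambiguous; no hit
anywhere leaves the surface unresolved with a blank gene id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from pinminer.corpus import AbstractRecord

FIELD_ORDER = ("official_symbol", "synonym", "full_name", "other_symbol", "locus_tag")

STRIPPABLE_ENDINGS = (
    "protein", "gene", "chain", "delta", "alpha", "beta", "gamma", "epsilon",
)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    taxon_id: str
    official_symbol: str
    synonyms: tuple[str, ...] = ()
    full_name: str = ""
    other_symbols: tuple[str, ...] = ()
    locus_tag: str = ""

    def field_values(self, field_name: str) -> tuple[str, ...]:
        value = getattr(self, {"synonym": "synonyms",
                               "other_symbol": "other_symbols"}.get(field_name, field_name))
        if isinstance(value, tuple):
            return value
        return (value,) if value else ()


@dataclass(frozen=True)
class NormalizedGene:
    surface: str
    gene_ids: tuple[str, ...] = ()
    official_symbol: str = ""
    taxon_id: str | None = None
    resolution_stage: str = "unresolved"

    def __post_init__(self) -> None:
        if bool(self.gene_ids) == (self.official_symbol == ""):
            raise ValueError("official_symbol blank iff gene_ids empty")

    @property
    def resolved(self) -> bool:
        return bool(self.gene_ids)

    @property
    def ambiguous(self) -> bool:
        return len(self.gene_ids) > 1

    @property
    def node_key(self) -> str:
        """Network node identity: official symbol, or surface when unresolved."""
        return self.official_symbol if self.resolved else self.surface


class GeneCatalog:
    """Gene records with per-taxon, per-field exact-match indexes."""

    def __init__(self, records: list[GeneRecord]):
        self.records = list(records)
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("gene_id values must be unique")
        # index[(taxon, field, case_sensitive)][key] -> list of records
        self._index: dict[tuple[str, str, bool], dict[str, list[GeneRecord]]] = {}
        for rec in self.records:
            for field_name in FIELD_ORDER:
                for value in rec.field_values(field_name):
                    for cs in (True, False):
                        key = value if cs else value.casefold()
                        bucket = self._index.setdefault(
                            (rec.taxon_id, field_name, cs), {})
                        bucket.setdefault(key, []).append(rec)

    def lookup(self, surface: str, taxa, field_name: str,
               case_sensitive: bool) -> list[GeneRecord]:
        key = surface if case_sensitive else surface.casefold()
        hits: list[GeneRecord] = []
        for taxon in taxa:
            bucket = self._index.get((taxon, field_name, case_sensitive), {})
            hits.extend(bucket.get(key, []))
        # deterministic order, de-duplicated by gene id
        seen: set[str] = set()
        out = []
        for rec in sorted(hits, key=lambda r: (r.taxon_id, r.gene_id)):
            if rec.gene_id not in seen:
                seen.add(rec.gene_id)
                out.append(rec)
        return out

    def synonyms_of(self, symbol: str) -> list[str]:
        """All synonyms of any record whose official symbol matches (any taxon)."""
        out: list[str] = []
        folded = symbol.casefold()
        for rec in self.records:
            if rec.official_symbol.casefold() == folded:
                out.extend(rec.synonyms)
        return out

    @classmethod
    def load(cls, path) -> "GeneCatalog":
        """Read a TSV mirroring NCBI gene_info columns.

        Columns: tax_id, GeneID, Symbol, Synonyms (pipe-separated, ``-``
        for none), description, Other_symbols (pipe-separated), LocusTag.
        Lines starting with ``#`` are skipped.
        """

        records = []
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 7:
                    raise ValueError(f"bad gene catalog line: {line!r}")
                records.append(GeneRecord(
                    taxon_id=cols[0], gene_id=cols[1], official_symbol=cols[2],
                    synonyms=_split_pipe(cols[3]), full_name=cols[4],
                    other_symbols=_split_pipe(cols[5]),
                    locus_tag="" if cols[6] == "-" else cols[6],
                ))
        return cls(records)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as out:
            out.write("#tax_id\tGeneID\tSymbol\tSynonyms\tdescription\t"
                      "Other_symbols\tLocusTag\n")
            for rec in self.records:
                out.write("\t".join([
                    rec.taxon_id, rec.gene_id, rec.official_symbol,
                    "|".join(rec.synonyms) or "-", rec.full_name,
                    "|".join(rec.other_symbols) or "-", rec.locus_tag or "-",
                ]) + "\n")


def _split_pipe(text: str) -> tuple[str, ...]:
    if not text or text == "-":
        return ()
    return tuple(t for t in text.split("|") if t)


class SpeciesIndex:
    """Case-insensitive map from scientific/common species names to taxon ids."""

    def __init__(self, names: dict[str, str]):
        self._map: dict[str, str] = {}
        for name, taxon in names.items():
            key = name.casefold()
            if key in self._map and self._map[key] != taxon:
                raise ValueError(f"species name {name!r} maps to two taxa")
            self._map[key] = taxon
        self._pattern = None
        if self._map:
            alts = sorted(self._map, key=len, reverse=True)
            self._pattern = re.compile(
                r"(?<![A-Za-z0-9])(" + "|".join(re.escape(a) for a in alts) +
                r")(?![A-Za-z0-9])", re.IGNORECASE)

    def __contains__(self, name: str) -> bool:
        return name.casefold() in self._map

    def taxon_of(self, name: str) -> str | None:
        return self._map.get(name.casefold())

    def find_all(self, text: str) -> list[str]:
        """Taxon ids of species names in text, in first-occurrence order."""
        if self._pattern is None:
            return []
        out = []
        for m in self._pattern.finditer(text):
            taxon = self._map[m.group(1).casefold()]
            if taxon not in out:
                out.append(taxon)
        return out

    @classmethod
    def load(cls, path) -> "SpeciesIndex":
        """Read TSV name/taxid pairs (names.dmp-style: name<TAB>taxon_id)."""
        names = {}
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                if not line.strip() or line.startswith("#"):
                    continue
                name, taxon = line.rstrip("\n").split("\t")[:2]
                names[name] = taxon
        return cls(names)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as out:
            for name in sorted(self._map):
                out.write(f"{name}\t{self._map[name]}\n")


# ---------------------------------------------------------------------------
# operations


def detect_species(record: AbstractRecord, index: SpeciesIndex) -> list[str]:
    """Taxon ids mentioned in title, body, or MeSH, first occurrence first."""

    found: list[str] = []
    for section in (record.title, record.body, "; ".join(record.mesh_terms)):
        for taxon in index.find_all(section):
            if taxon not in found:
                found.append(taxon)
    return found


_TRAILING_DIGIT = re.compile(r"^(.*\S)\s+(\d+)$")
_RECEPTOR = re.compile(r"^(.*\S)\s+receptor$", re.IGNORECASE)


def transform_variants(surface: str) -> list[str]:
    """Rule-based surface variants, in rule order, original excluded.

    Rules: join a detached trailing number ("XXX 1" → "XXX1"); abbreviate
    a trailing "receptor" ("XXX receptor" → "XXXR"); strip one trailing
    general ending from {protein, gene, chain, delta, alpha, beta, gamma,
    epsilon}.
    """

    surface = surface.strip()
    if not surface:
        raise ValueError("empty surface")
    variants: list[str] = []

    m = _TRAILING_DIGIT.match(surface)
    if m:
        variants.append(m.group(1) + m.group(2))

    m = _RECEPTOR.match(surface)
    if m:
        variants.append(m.group(1) + "R")

    tokens = surface.split()
    if len(tokens) > 1 and tokens[-1].casefold() in STRIPPABLE_ENDINGS:
        variants.append(" ".join(tokens[:-1]))

    seen: set[str] = set()
    out = []
    for v in variants:
        if v != surface and v not in seen:
            seen.add(v)
            out.append(v)
    return out


def _match_stage(surface: str, taxa, catalog: GeneCatalog,
                 case_sensitive: bool) -> list[GeneRecord]:
    for field_name in FIELD_ORDER:
        hits = catalog.lookup(surface, taxa, field_name, case_sensitive)
        if hits:
            return hits
    return []


def normalize_mention(surface: str, taxa, catalog: GeneCatalog) -> NormalizedGene:
    """Resolve a tagged surface form through the normalization cascade."""

    if not taxa:
        raise ValueError("at least one taxon id required (apply default upstream)")

    attempts = [
        (surface, True, "cs_exact"),
        (surface, False, "ci_exact"),
    ]
    for variant in transform_variants(surface):
        attempts.append((variant, True, "cs_transformed"))
        attempts.append((variant, False, "ci_transformed"))

    for candidate, case_sensitive, stage in attempts:
        hits = _match_stage(candidate, taxa, catalog, case_sensitive)
        if hits:
            return NormalizedGene(
                surface=surface,
                gene_ids=tuple(r.gene_id for r in hits),
                official_symbol=hits[0].official_symbol,
                taxon_id=hits[0].taxon_id,
                resolution_stage=stage,
            )
    return NormalizedGene(surface=surface)
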