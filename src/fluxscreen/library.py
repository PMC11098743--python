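"""Transporter sgRNA library model and the pseudogene (simulated NTC gene) null.

The screening library targets the solute-carrier (SLC), atypical SLC and
ATP-binding-cassette (ABC) transporter families with 10 sgRNAs per
transcription start site (TSS), a subset of genes carrying two TSSs, plus a
pool of non-targeting control (NTC) sgRNAs. Significance calibration relies
on "pseudogenes": random groups of NTC sgRNAs scored exactly like real genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientNTCError, InvalidSpecError

#: Sentinel gene name carried by every non-targeting control sgRNA.
NTC_GENE = "NTC"

#: Gene counts per transporter class as screened in K562 cells
#: (413 SLC + 28 atypical SLC + 48 ABC = 489 target genes).
DEFAULT_COMPOSITION: dict[str, int] = {"SLC": 413, "atypical_SLC": 28, "ABC": 48}

#: Library-wide defaults: sgRNAs per TSS, genes with two TSSs, NTC pool size.
DEFAULT_SGRNAS_PER_TSS = 10
DEFAULT_TWO_TSS_GENES = 37
DEFAULT_N_NTC = 730

_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class SgRNAEntry:
    """One sgRNA: identifier, target gene (or NTC sentinel), TSS tag, protospacer."""

    sgrna_id: str
    gene: str
    tss: str
    protospacer: str
    is_ntc: bool

    def __post_init__(self):
        if self.is_ntc != (self.gene == NTC_GENE):
            raise InvalidSpecError(
                f"{self.sgrna_id}: is_ntc must be equivalent to gene == {NTC_GENE!r}"
            )
        if not (19 <= len(self.protospacer) <= 20) or set(self.protospacer) - set("ACGT"):
            raise InvalidSpecError(
                f"{self.sgrna_id}: protospacer must be 19-20 nt over A/C/G/T"
            )
        if self.tss not in ("primary", "secondary"):
            raise InvalidSpecError(f"{self.sgrna_id}: tss must be primary or secondary")


@dataclass
class LibraryManifest:
    """The full sgRNA library: entries plus per-class composition counts."""

    entries: list[SgRNAEntry]
    composition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        ids = [e.sgrna_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise InvalidSpecError("sgrna_id values must be unique within a manifest")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        """Distinct non-NTC target genes, in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.entries:
            if not e.is_ntc:
                seen.setdefault(e.gene, None)
        return list(seen)

    @property
    def ntc_ids(self) -> list[str]:
        return [e.sgrna_id for e in self.entries if e.is_ntc]

    @property
    def two_tss_genes(self) -> list[str]:
        secondary = {e.gene for e in self.entries if e.tss == "secondary" and not e.is_ntc}
        return [g for g in self.genes if g in secondary]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sgrna_id": [e.sgrna_id for e in self.entries],
                "gene": [e.gene for e in self.entries],
                "tss": [e.tss for e in self.entries],
                "protospacer": [e.protospacer for e in self.entries],
                "is_ntc": [e.is_ntc for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LibraryManifest":
        df = pd.read_csv(path, dtype={"sgrna_id": str, "gene": str, "tss": str})
        entries = [
            SgRNAEntry(r.sgrna_id, r.gene, r.tss, r.protospacer, bool(r.is_ntc))
            for r in df.itertuples(index=False)
        ]
        return cls(entries)


@dataclass(frozen=True)
class PseudogeneAssignment:
    """A simulated negative-control gene: a random group of NTC sgRNAs."""

    pseudogene_id: str
    member_sgrna_ids: tuple[str, ...]
    seed: int

    def __post_init__(self):
        if len(set(self.member_sgrna_ids)) != len(self.member_sgrna_ids):
            raise InvalidSpecError(f"{self.pseudogene_id}: members must be distinct")


def _random_protospacers(n: int, rng: np.random.Generator) -> list[str]:
    """Unique random 19/20-nt protospacers (sequences are synthetic placeholders)."""
    out: dict[str, None] = {}
    while len(out) < n:
        need = n - len(out)
        lengths = rng.integers(19, 21, size=need)
        chars = rng.integers(0, 4, size=(need, 20))
        for length, row in zip(lengths, chars):
            out.setdefault("".join(_DNA[row[:length]]), None)
    return list(out)[:n]


def build_manifest(
    composition: dict[str, int] | None = None,
    sgrnas_per_tss: int = DEFAULT_SGRNAS_PER_TSS,
    two_tss_genes: int = DEFAULT_TWO_TSS_GENES,
    n_ntc: int = DEFAULT_N_NTC,
    seed: int = 0,
) -> LibraryManifest:
    """Build a synthetic manifest with the given class composition.

    ``composition`` maps transporter class to gene count (default: the
    489-gene SLC/atypical-SLC/ABC screening composition). ``two_tss_genes``
    genes receive a second TSS block of ``sgrnas_per_tss`` sgRNAs each.
    Deterministic for a given seed.
    """
    if composition is None:
        composition = dict(DEFAULT_COMPOSITION)
    if sgrnas_per_tss <= 0:
        raise InvalidSpecError("sgrnas_per_tss must be positive")
    if any(c <= 0 for c in composition.values()) or not composition:
        raise InvalidSpecError("all class gene counts must be positive")
    if two_tss_genes < 0 or n_ntc < 0:
        raise InvalidSpecError("two_tss_genes and n_ntc must be non-negative")
    n_genes = sum(composition.values())
    if two_tss_genes > n_genes:
        raise InvalidSpecError("two_tss_genes cannot exceed the total gene count")

    rng = np.random.default_rng(seed)
    genes: list[str] = []
    for cls_name, count in composition.items():
        genes.extend(f"{cls_name}{i + 1:03d}" for i in range(count))
    two_tss = set(rng.choice(n_genes, size=two_tss_genes, replace=False).tolist())

    n_targeting = (n_genes - two_tss_genes) * sgrnas_per_tss + two_tss_genes * 2 * sgrnas_per_tss
    spacers = iter(_random_protospacers(n_targeting + n_ntc, rng))

    entries: list[SgRNAEntry] = []
    for gi, gene in enumerate(genes):
        tss_tags = ("primary", "secondary") if gi in two_tss else ("primary",)
        for tss in tss_tags:
            for k in range(sgrnas_per_tss):
                entries.append(
                    SgRNAEntry(f"{gene}_{tss}_{k + 1:02d}", gene, tss, next(spacers), False)
                )
    for k in range(n_ntc):
        entries.append(SgRNAEntry(f"NTC_{k + 1:04d}", NTC_GENE, "primary", next(spacers), True))

    comp = dict(composition)
    comp["NTC"] = n_ntc
    return LibraryManifest(entries, comp)


def make_pseudogenes(
    manifest: LibraryManifest,
    n_pseudogenes: int,
    size: int = 10,
    seed: int = 0,
) -> list[PseudogeneAssignment]:
    """Randomly group NTC sgRNAs into ``n_pseudogenes`` simulated genes.

    Members are drawn without replacement within a pseudogene; the same NTC
    sgRNA may recur across pseudogenes (the NTC pool is smaller than
    n_pseudogenes * size under the screening composition). Reproducible
    under ``seed``.
    """
    ntc = manifest.ntc_ids
    if size > len(ntc):
        raise InsufficientNTCError(
            f"pseudogene size {size} exceeds the NTC pool of {len(ntc)} sgRNAs"
        )
    if n_pseudogenes <= 0 or size <= 0:
        raise InvalidSpecError("n_pseudogenes and size must be positive")
    rng = np.random.default_rng(seed)
    ntc_arr = np.asarray(ntc, dtype=object)
    out = []
    for i in range(n_pseudogenes):
        members = rng.choice(ntc_arr, size=size, replace=False)
        out.append(PseudogeneAssignment(f"pseudo_{i + 1:04d}", tuple(members), seed))
    return out


def pseudogenes_to_csv(assignments: list[PseudogeneAssignment], path) -> None:
    pd.DataFrame(
        {
            "pseudogene_id": [a.pseudogene_id for a in assignments],
            "member_sgrna_ids": [";".join(a.member_sgrna_ids) for a in assignments],
        }
    ).to_csv(path, index=False)


def pseudogenes_from_csv(path, seed: int = -1) -> list[PseudogeneAssignment]:
    df = pd.read_csv(path)
    return [
        PseudogeneAssignment(r.pseudogene_id, tuple(r.member_sgrna_ids.split(";")), seed)
        for r in df.itertuples(index=False)
    ]
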