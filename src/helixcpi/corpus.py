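"""Dataset construction for class A GPCR compound-protein interactions.

Interaction tables (GLASS-style TSV), receptor sequences (FASTA),
UniProt-style region annotations and a class-A membership list are
parsed into plain records; affinities are converted to molar, labelled
by the pAff >= 6 rule, filtered for ligand bias, and split into
reproducible train/validation/test partitions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

TM_REGIONS = tuple(f"TM{i}" for i in range(1, 8))
ECL_REGIONS = ("ECL1", "ECL2", "ECL3")
POSITIVE_PAFF_THRESHOLD = 6.0
ALLOWED_AFFINITY_TYPES = frozenset({"IC50", "EC50"})

#: multiplicative factors to mol/L
UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


class Region(NamedTuple):
    region_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive


@dataclass(frozen=True)
class ReceptorRecord:
    """A receptor sequence with named-region coordinates.

    ``regions`` must contain all of TM1..TM7 in ascending, non-overlapping
    coordinate order; extracellular loops ECL1..ECL3 are optional.
    """

    accession: str
    sequence: str
    regions: tuple[Region, ...]
    subfamily: str | None = None

    def __post_init__(self):
        by_id = {r.region_id: r for r in self.regions}
        missing = [t for t in TM_REGIONS if t not in by_id]
        if missing:
            raise ValueError(f"{self.accession}: missing region {missing[0]}")
        for r in self.regions:
            if not (1 <= r.start <= r.end <= len(self.sequence)):
                raise ValueError(
                    f"{self.accession}: region {r.region_id} coordinates "
                    f"({r.start},{r.end}) outside sequence of length {len(self.sequence)}")
        ordered = sorted(self.regions, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise ValueError(
                    f"{self.accession}: regions {a.region_id} and {b.region_id} overlap")
        tm_starts = [by_id[t].start for t in TM_REGIONS]
        if tm_starts != sorted(tm_starts):
            raise ValueError(f"{self.accession}: TM1..TM7 not in ascending order")

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"{self.accession}: missing region {region_id}")

    def region_sequence(self, region_id: str) -> str:
        r = self.region(region_id)
        return self.sequence[r.start - 1:r.end]


@dataclass(frozen=True)
class InteractionRecord:
    accession: str
    smiles: str
    affinity_type: str
    affinity_molar: float
    label: str  # "positive" | "negative"

    @property
    def y(self) -> int:
        return 1 if self.label == "positive" else 0


@dataclass(frozen=True)
class SplitSpec:
    seed: int = 0
    train_frac: float = 0.8
    test_frac: float = 0.2
    val_frac_of_train: float = 0.2
    mode: str = "random"  # or "protein_disjoint"

    def __post_init__(self):
        if not (0 < self.train_frac < 1 and 0 < self.test_frac < 1):
            raise ValueError("fractions must lie in (0,1)")
        if abs(self.train_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("train_frac + test_frac must equal 1")
        if self.mode not in ("random", "protein_disjoint"):
            raise ValueError(f"unknown split mode {self.mode!r}")


@dataclass(frozen=True)
class DatasetSummary:
    n_proteins: int
    n_compounds: int
    n_interactions: int
    n_positive: int
    n_negative: int


def paff(affinity_molar: float) -> float:
    """Negative base-10 log of a molar affinity (pIC50/pEC50)."""
    return -math.log10(affinity_molar)


def label_interaction(affinity_molar: float) -> str:
    """Binary activity label: positive iff pAff >= 6 (i.e. <= 1 uM)."""
    if not (isinstance(affinity_molar, (int, float))
            and math.isfinite(affinity_molar) and affinity_molar > 0):
        raise ValueError(f"affinity must be positive and finite, got {affinity_molar!r}")
    return "positive" if paff(affinity_molar) >= POSITIVE_PAFF_THRESHOLD else "negative"


def load_interactions(path: str | Path, default_unit: str = "M") -> list[InteractionRecord]:
    """Read an interaction TSV and return labelled records.

    Expected columns: accession, smiles, affinity_type, affinity_value
    and optionally unit (falling back to ``default_unit``). Rows with
    an affinity type other than IC50/EC50, a non-positive or non-finite
    affinity, or an unknown unit are dropped with a logged reason.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    records: list[InteractionRecord] = []
    for row in df.itertuples(index=False):
        unit = getattr(row, "unit", default_unit) or default_unit
        atype = row.affinity_type
        if atype not in ALLOWED_AFFINITY_TYPES:
            logger.info("dropping %s/%s: affinity type %r not IC50/EC50",
                        row.accession, row.smiles, atype)
            continue
        if unit not in UNIT_TO_MOLAR:
            logger.warning("dropping %s/%s: unknown unit %r", row.accession, row.smiles, unit)
            continue
        try:
            value = float(row.affinity_value)
            molar = value * UNIT_TO_MOLAR[unit]
            label = label_interaction(molar)
        except (TypeError, ValueError) as exc:
            logger.warning("dropping %s/%s: %s", row.accession, row.smiles, exc)
            continue
        records.append(InteractionRecord(row.accession, row.smiles, atype, molar, label))
    return records


def load_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_regions(path: str | Path) -> dict[str, tuple[Region, ...]]:
    """Region-annotation TSV: accession, region_id, start, end (1-based)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[Region]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.accession, []).append(
            Region(row.region_id, int(row.start), int(row.end)))
    return {k: tuple(v) for k, v in out.items()}


def load_membership(path: str | Path) -> set[str]:
    lines = Path(path).read_text().split()
    return {line.strip() for line in lines if line.strip()}


def load_receptors(fasta_path, regions_path,
                   subfamilies: Mapping[str, str] | None = None) -> dict[str, ReceptorRecord]:
    seqs = load_fasta(fasta_path)
    regions = load_regions(regions_path)
    receptors = {}
    for acc, seq in seqs.items():
        if acc not in regions:
            logger.warning("no region annotations for %s; skipped", acc)
            continue
        sub = subfamilies.get(acc) if subfamilies else None
        receptors[acc] = ReceptorRecord(acc, seq, regions[acc], sub)
    return receptors


def filter_class_a(records: Sequence[InteractionRecord],
                   membership: Iterable[str]) -> list[InteractionRecord]:
    """Keep only records whose accession is in the class-A membership set."""
    members = set(membership)
    if not members:
        raise ValueError("class-A membership set is empty")
    return [r for r in records if r.accession in members]


def deduplicate(records: Sequence[InteractionRecord]) -> list[InteractionRecord]:
    """Collapse identical (accession, SMILES) pairs.

    Pairs whose duplicate records agree in label are kept once (first
    in canonical order); pairs with contradictory labels are dropped
    entirely as noise.
    """
    groups: dict[tuple[str, str], list[InteractionRecord]] = {}
    for r in sorted(records, key=lambda r: (r.accession, r.smiles, -paff(r.affinity_molar))):
        groups.setdefault((r.accession, r.smiles), []).append(r)
    out = []
    for key, grp in groups.items():
        labels = {g.label for g in grp}
        if len(labels) > 1:
            logger.info("dropping %s: contradictory duplicate labels", key)
            continue
        out.append(grp[0])
    return out


def filter_ligand_bias(records: Sequence[InteractionRecord]) -> list[InteractionRecord]:
    """Remove ligand-biased compounds, iterating to a fixed point.

    A compound is removed if it has only one surviving interaction or if
    all its surviving interactions carry the same label (it "exists only
    in one class"), since such compounds let the model predict from the
    ligand alone. Removal can create new single-interaction compounds,
    so the filter repeats until nothing changes.
    """
    current = list(records)
    while True:
        by_smiles: dict[str, list[InteractionRecord]] = {}
        for r in current:
            by_smiles.setdefault(r.smiles, []).append(r)
        keep = {s for s, grp in by_smiles.items()
                if len(grp) >= 2 and len({g.label for g in grp}) == 2}
        nxt = [r for r in current if r.smiles in keep]
        if len(nxt) == len(current):
            break
        current = nxt
    if not current:
        logger.warning("ligand-bias filter removed every record")
    return current


def prepare_dataset(records: Sequence[InteractionRecord],
                    membership: Iterable[str]) -> list[InteractionRecord]:
    """Full cleaning pipeline: class-A filter, dedup, ligand-bias filter."""
    records = filter_class_a(records, membership)
    records = deduplicate(records)
    return filter_ligand_bias(records)


def _canonical_sort(records: Sequence[InteractionRecord]) -> list[InteractionRecord]:
    return sorted(records, key=lambda r: (r.accession, r.smiles))


def make_splits(records: Sequence[InteractionRecord], spec: SplitSpec
                ) -> tuple[list[InteractionRecord], list[InteractionRecord], list[InteractionRecord]]:
    """Partition records into (train, validation, test).

    Records are canonically sorted (accession, SMILES) before the
    seeded shuffle so the partition is independent of input file order.
    In ``protein_disjoint`` mode whole accessions are assigned to the
    test side until it holds ~test_frac of the records, so no protein
    is shared between train+validation and test.
    """
    records = _canonical_sort(records)
    n = len(records)
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "random":
        order = rng.permutation(n)
        n_test = int(round(spec.test_frac * n))
        test = [records[i] for i in order[:n_test]]
        rest = [records[i] for i in order[n_test:]]
    else:
        accessions = sorted({r.accession for r in records})
        acc_order = rng.permutation(len(accessions))
        target = spec.test_frac * n
        by_acc: dict[str, list[InteractionRecord]] = {}
        for r in records:
            by_acc.setdefault(r.accession, []).append(r)
        test_accs: set[str] = set()
        count = 0
        for i in acc_order:
            if count >= target:
                break
            acc = accessions[i]
            test_accs.add(acc)
            count += len(by_acc[acc])
        test = [r for r in records if r.accession in test_accs]
        rest = [r for r in records if r.accession not in test_accs]
        perm = rng.permutation(len(rest))
        rest = [rest[i] for i in perm]
    n_val = int(round(spec.val_frac_of_train * len(rest)))
    val = rest[:n_val]
    train = rest[n_val:]
    if not (train and val and test):
        raise ValueError(
            f"too few records ({n}) to populate train/validation/test")
    return train, val, test


def summarize(records: Sequence[InteractionRecord]) -> DatasetSummary:
    n_pos = sum(1 for r in records if r.label == "positive")
    return DatasetSummary(
        n_proteins=len({r.accession for r in records}),
        n_compounds=len({r.smiles for r in records}),
        n_interactions=len(records),
        n_positive=n_pos,
        n_negative=len(records) - n_pos,
    )


def write_split(records: Sequence[InteractionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.accession, r.smiles, r.affinity_type, r.affinity_molar, r.label)
         for r in records],
        columns=["accession", "smiles", "affinity_type", "affinity_molar", "label"])
    df.to_csv(path, sep="\t", index=False)


def read_split(path: str | Path) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t")
    return [InteractionRecord(r.accession, r.smiles, r.affinity_type,
                              float(r.affinity_molar), r.label)
            for r in df.itertuples(index=False)]


def write_split_manifest(out_dir: str | Path, spec: SplitSpec,
                         splits: Mapping[str, Sequence[InteractionRecord]]) -> None:
    out_dir = Path(out_dir)
    manifest = {"seed": spec.seed, "mode": spec.mode, "counts": {}}
    for name, recs in splits.items():
        write_split(recs, out_dir / f"{name}.tsv")
        s = summarize(recs)
        manifest["counts"][name] = {
            "proteins": s.n_proteins, "compounds": s.n_compounds,
            "interactions": s.n_interactions,
            "positive": s.n_positive, "negative": s.n_negative}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
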