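"""Chromosome morphometry: karyotypes, Levan classes, and asymmetry.

Arm-length measurements from mitotic metaphase spreads are turned into an
ordered karyotype (chromosomes ranked by decreasing mean length across
cells), each chromosome is classified by its arm ratio following Levan's
nomenclature, and the record is summarised as a karyotype formula string
like ``2n = 2x = 10 = 4m + 4sm + 2st``.

Karyotype heterogeneity is quantified by the asymmetry index

    AI = CV_CL * CV_CI / 100

where ``CV_CL`` is the coefficient of variation (in percent) of the 2n
chromosome lengths and ``CV_CI`` that of the centromeric indices
(CI = 100 * short arm / total length).  AI is 0 for a perfectly uniform
karyotype and is invariant to rescaling all lengths.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: Levan-type arm-ratio class boundaries.  Boundaries belong to the more
#: symmetric class (r = 1.7 is still 'm', r = 3.0 still 'sm', r = 7.0 still
#: 'st').
CLASS_ORDER = ("m", "sm", "st", "t")
_CLASS_UPPER = {"m": 1.7, "sm": 3.0, "st": 7.0}


class KaryotypeError(ValueError):
    pass


@dataclass(frozen=True)
class ChromosomeMeasurement:
    """One measured chromosome: cell id, chromosome id, arm lengths in µm.

    Long and short arms are swapped on construction if given in the wrong
    order, so ``long_um >= short_um`` always holds.
    """

    cell_id: str
    chrom_id: str
    long_um: float
    short_um: float

    def __post_init__(self):
        if self.long_um <= 0 or self.short_um <= 0:
            raise KaryotypeError(
                f"arm lengths must be positive (cell {self.cell_id}, "
                f"chromosome {self.chrom_id})"
            )
        if self.short_um > self.long_um:
            long_arm, short_arm = self.short_um, self.long_um
            object.__setattr__(self, "long_um", long_arm)
            object.__setattr__(self, "short_um", short_arm)

    @property
    def total_um(self) -> float:
        return self.long_um + self.short_um

    @property
    def arm_ratio(self) -> float:
        return self.long_um / self.short_um

    @property
    def centromeric_index(self) -> float:
        return 100.0 * self.short_um / self.total_um


def classify_chromosome(long_um: float, short_um: float) -> str:
    """Levan-type class from the arm ratio r = long/short.

    m for r in [1, 1.7], sm for (1.7, 3], st for (3, 7], t above 7.
    """
    if long_um <= 0 or short_um <= 0:
        raise KaryotypeError("arm lengths must be positive")
    if short_um > long_um:
        long_um, short_um = short_um, long_um
    r = long_um / short_um
    for cls in ("m", "sm", "st"):
        if r <= _CLASS_UPPER[cls]:
            return cls
    return "t"


@dataclass
class KaryotypeRecord:
    """Ordered karyotype of one accession with morphometry statistics."""

    taxon: str
    two_n: int
    ploidy: int
    lengths_um: np.ndarray  # 2n mean total lengths, decreasing
    centromeric_indices: np.ndarray  # 2n values, 0 < CI <= 50
    classes: list[str]  # per chromosome, aligned with lengths
    n_cells: int = 0

    def __post_init__(self):
        self.lengths_um = np.asarray(self.lengths_um, dtype=float)
        self.centromeric_indices = np.asarray(self.centromeric_indices, dtype=float)
        if self.two_n % 2 or self.two_n <= 0:
            raise KaryotypeError(f"2n must be an even positive integer, got {self.two_n}")
        if self.two_n % self.ploidy:
            raise KaryotypeError(f"2n={self.two_n} not divisible by ploidy {self.ploidy}")
        if len(self.lengths_um) != self.two_n:
            raise KaryotypeError("number of chromosomes does not match 2n")
        if np.any(np.diff(self.lengths_um) > 1e-12):
            raise KaryotypeError("chromosome lengths must be sorted non-increasing")

    @property
    def base_number(self) -> int:
        """x = 2n / ploidy."""
        return self.two_n // self.ploidy

    @property
    def class_counts(self) -> dict[str, int]:
        return {c: self.classes.count(c) for c in CLASS_ORDER if c in self.classes}

    @property
    def formula(self) -> str:
        return render_formula(self.two_n, self.ploidy, self.class_counts)

    # Eq-style symbols: X mean, S sample SD, CV = 100*S/X
    @property
    def cv_cl(self) -> float:
        return _cv(self.lengths_um)

    @property
    def cv_ci(self) -> float:
        return _cv(self.centromeric_indices)

    @property
    def asymmetry_index(self) -> float:
        return self.cv_cl * self.cv_ci / 100.0


def _cv(values: np.ndarray, ddof: int = 1) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise KaryotypeError("need at least 2 chromosomes for a CV")
    return 100.0 * float(np.std(values, ddof=ddof)) / float(np.mean(values))


def asymmetry_index(record: KaryotypeRecord, ddof: int = 1) -> tuple[float, float, float]:
    """(CV_CL, CV_CI, AI) for a karyotype.

    ``ddof=1`` (sample standard deviation) is the default; pass 0 for the
    population convention.  Statistics run over all 2n chromosomes.
    """
    cv_cl = _cv(record.lengths_um, ddof)
    cv_ci = _cv(record.centromeric_indices, ddof)
    return cv_cl, cv_ci, cv_cl * cv_ci / 100.0


def render_formula(two_n: int, ploidy: int, class_counts: Mapping[str, int]) -> str:
    """``2n = <ploidy>x = <2n> = 4m + 4sm + 2st`` with zero classes omitted."""
    total = sum(class_counts.values())
    if total != two_n:
        raise KaryotypeError(f"class counts sum to {total}, expected 2n = {two_n}")
    parts = [f"{class_counts[c]}{c}" for c in CLASS_ORDER if class_counts.get(c)]
    return f"2n = {ploidy}x = {two_n} = " + " + ".join(parts)


_FORMULA_RE = re.compile(
    r"^\s*2n\s*=\s*(\d+)x\s*=\s*(\d+)\s*=\s*(.+)$"
)
_TERM_RE = re.compile(r"^(\d+)\s*(m|sm|st|t)$")


def parse_formula(formula: str) -> tuple[int, int, dict[str, int]]:
    """Inverse of :func:`render_formula`: (2n, ploidy, class counts)."""
    m = _FORMULA_RE.match(formula)
    if not m:
        raise KaryotypeError(f"cannot parse karyotype formula {formula!r}")
    ploidy, two_n = int(m.group(1)), int(m.group(2))
    counts: dict[str, int] = {}
    for term in m.group(3).split("+"):
        t = _TERM_RE.match(term.strip())
        if not t:
            raise KaryotypeError(f"bad term {term.strip()!r} in formula {formula!r}")
        counts[t.group(2)] = counts.get(t.group(2), 0) + int(t.group(1))
    if sum(counts.values()) != two_n:
        raise KaryotypeError(
            f"formula {formula!r}: class counts sum to {sum(counts.values())}, "
            f"expected {two_n}"
        )
    return two_n, ploidy, counts


def build_karyotype(
    measurements: Iterable[ChromosomeMeasurement],
    two_n: int,
    ploidy: int = 2,
    taxon: str = "",
    min_cells: int = 10,
) -> KaryotypeRecord:
    """Average per-cell measurements into an ordered karyotype.

    Within each cell the chromosomes are sorted by decreasing total length;
    rank-wise means of the long and short arms across cells give the
    karyotype.  Homologues are paired as consecutive ranks.  Every cell must
    contribute exactly 2n chromosomes; fewer than ``min_cells`` cells only
    warns (the morphometric convention asks for at least ten good metaphase
    spreads, but smaller inputs are still well defined).
    """
    by_cell: dict[str, list[ChromosomeMeasurement]] = {}
    for m in measurements:
        by_cell.setdefault(m.cell_id, []).append(m)
    if not by_cell:
        raise KaryotypeError("no measurements given")
    for cell, chroms in by_cell.items():
        if len(chroms) != two_n:
            raise KaryotypeError(
                f"cell {cell!r} has {len(chroms)} chromosomes, expected 2n = {two_n}"
            )
    if len(by_cell) < min_cells:
        warnings.warn(
            f"only {len(by_cell)} cells measured (recommended >= {min_cells})",
            stacklevel=2,
        )
    longs = np.empty((len(by_cell), two_n))
    shorts = np.empty_like(longs)
    for i, chroms in enumerate(by_cell.values()):
        ranked = sorted(chroms, key=lambda c: -c.total_um)
        longs[i] = [c.long_um for c in ranked]
        shorts[i] = [c.short_um for c in ranked]
    mean_long = longs.mean(axis=0)
    mean_short = shorts.mean(axis=0)
    totals = mean_long + mean_short
    order = np.argsort(-totals, kind="stable")
    mean_long, mean_short, totals = mean_long[order], mean_short[order], totals[order]
    classes = [classify_chromosome(l, s) for l, s in zip(mean_long, mean_short)]
    cis = 100.0 * mean_short / totals
    return KaryotypeRecord(
        taxon=taxon,
        two_n=two_n,
        ploidy=ploidy,
        lengths_um=totals,
        centromeric_indices=cis,
        classes=classes,
        n_cells=len(by_cell),
    )


@dataclass(frozen=True)
class BaseNumberRecord:
    """Minimal record for base-number tallies."""

    species: str
    base_number: int
    infraspecific: str = ""
    ploidy: int = 2


def tally_base_numbers(
    records: Iterable[BaseNumberRecord],
    merge_infraspecific: bool = True,
) -> dict[int, int]:
    """Count species per haploid base number x.

    Accessions collapse onto their species; with ``merge_infraspecific``
    subspecies collapse too.  A species observed (in distinct diploid
    accessions) with conflicting x is counted once under each distinct x and
    reported via a warning.
    """
    seen: dict[str, set[int]] = {}
    for r in records:
        key = r.species if merge_infraspecific else f"{r.species}|{r.infraspecific}"
        seen.setdefault(key, set()).add(r.base_number)
    tally: dict[int, int] = {}
    for sp, xs in seen.items():
        if len(xs) > 1:
            warnings.warn(
                f"species {sp!r} has conflicting base numbers {sorted(xs)}",
                stacklevel=2,
            )
        for x in xs:
            tally[x] = tally.get(x, 0) + 1
    return dict(sorted(tally.items()))
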