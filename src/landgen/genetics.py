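"""Genotype input and individual pairwise genetic / geographic distances.

Gene flow between individuals is summarized by two microsatellite distance
metrics: Dps (one minus the proportion of shared alleles across loci) and
Rousset's a, the between-individual analogue of Fst/(1-Fst) that is expected
to increase linearly with distance under isolation by distance.  Straight-line
geographic distance completes the trio used by the Mantel machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = (0, 0)


class GeneticsError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Diploid genotypes at L loci for n georeferenced individuals.

    ``calls`` has shape (n, L, 2); allele code 0 denotes missing (a call is
    missing iff both alleles are 0, the GenePop "000" convention).
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    coords: np.ndarray  # (n, 2) projected x/y in meters
    area_tag: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise GeneticsError(f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        if self.coords.shape != (n, 2):
            raise GeneticsError("coords shape mismatch")
        if n < 2:
            raise GeneticsError("need at least 2 individuals")
        if len(set(self.individuals)) != n:
            raise GeneticsError("duplicate individual labels")
        if not np.all(np.isfinite(self.coords)):
            raise GeneticsError("coordinates must be finite")
        half_missing = (self.calls == 0).sum(axis=2) == 1
        if half_missing.any():
            i, l = np.argwhere(half_missing)[0]
            raise GeneticsError(
                f"half-missing call for {self.individuals[i]} at locus {self.loci[l]}"
            )

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """(n, L) True where the call is missing."""
        return (self.calls == 0).all(axis=2)

    def subset(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            [self.individuals[i] for i in idx],
            list(self.loci),
            self.calls[idx],
            self.coords[idx],
            [self.area_tag[i] for i in idx] if self.area_tag else None,
        )


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix over individuals, tagged by kind."""

    labels: list[str]
    values: np.ndarray
    kind: str  # genetic_a | genetic_dps | geographic | effective

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise GeneticsError("distance matrix shape mismatch")
        finite = np.isfinite(self.values)
        if not np.allclose(self.values[finite], self.values.T[finite.T]):
            raise GeneticsError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise GeneticsError("distance matrix diagonal must be zero")
        if self.kind == "genetic_dps":
            if np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12:
                raise GeneticsError("Dps must lie in [0, 1]")
        if self.kind in {"geographic", "effective"}:
            if np.nanmin(self.values[finite]) < -1e-12:
                raise GeneticsError(f"{self.kind} distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path, kind: str) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), kind)


# ---------------------------------------------------------------------------
# GenePop I/O
# ---------------------------------------------------------------------------


def read_genotypes(genepop_path, coords_path=None, coords: pd.DataFrame | None = None) -> GenotypeTable:
    """Parse a GenePop file (2- or 3-digit allele codes) plus coordinates.

    Coordinates come from a CSV with columns ``individual, x, y`` (and
    optionally ``area``), joined on the individual label.  Population
    separators ("POP") are honored; population membership is recorded in
    ``area_tag`` when no explicit area column is given.
    """
    with open(genepop_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise GeneticsError("empty GenePop file")
    # line 0 is the title; locus names follow until the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        ln = lines[i].strip()
        if ln:
            # loci may be one per line or comma-separated
            loci.extend(s.strip() for s in ln.split(",") if s.strip())
        i += 1
    if not loci:
        raise GeneticsError("no locus names found")
    individuals: list[str] = []
    calls_rows: list[list[tuple[int, int]]] = []
    pops: list[str] = []
    pop_idx = 0
    while i < len(lines):
        ln = lines[i].strip()
        i += 1
        if not ln:
            continue
        if ln.upper() == "POP":
            pop_idx += 1
            continue
        if "," not in ln:
            raise GeneticsError(f"malformed GenePop line (no comma): {ln!r}")
        label, rest = ln.split(",", 1)
        label = label.strip()
        codes = rest.split()
        if len(codes) != len(loci):
            raise GeneticsError(
                f"individual {label!r}: {len(codes)} genotypes for {len(loci)} loci"
            )
        row = []
        for code in codes:
            if len(code) not in (4, 6) or len(code) % 2:
                raise GeneticsError(f"individual {label!r}: bad allele code length {code!r}")
            half = len(code) // 2
            a, b = int(code[:half]), int(code[half:])
            if (a == 0) != (b == 0):
                raise GeneticsError(f"individual {label!r}: half-missing code {code!r}")
            row.append((a, b))
        individuals.append(label)
        calls_rows.append(row)
        pops.append(f"pop{pop_idx}")
    if len(set(individuals)) != len(individuals):
        raise GeneticsError("duplicate individual labels in GenePop file")
    if coords is None:
        if coords_path is None:
            raise GeneticsError("coordinates required (coords_path or coords)")
        coords = pd.read_csv(coords_path)
    coords = coords.set_index(coords.columns[0]) if coords.index.name is None and "individual" not in coords.columns else coords
    if "individual" in coords.columns:
        coords = coords.set_index("individual")
    coords.index = coords.index.astype(str)
    missing = [ind for ind in individuals if ind not in coords.index]
    if missing:
        raise GeneticsError(f"individuals missing coordinates: {missing}")
    xy = coords.loc[individuals, ["x", "y"]].to_numpy(float)
    area = (
        list(coords.loc[individuals, "area"].astype(str))
        if "area" in coords.columns
        else pops
    )
    return GenotypeTable(individuals, loci, np.array(calls_rows, int), xy, area)


def write_genotypes(g: GenotypeTable, genepop_path, coords_path=None, title="landgen export") -> None:
    """Write GenePop (3-digit codes) and, optionally, the coordinate CSV."""
    width = 3 if int(g.calls.max(initial=0)) > 99 else 3  # always 3-digit: lossless
    with open(genepop_path, "w") as fh:
        fh.write(title + "\n")
        for locus in g.loci:
            fh.write(locus + "\n")
        areas = g.area_tag or ["pop0"] * g.n
        prev = None
        for i, ind in enumerate(g.individuals):
            if areas[i] != prev:
                fh.write("POP\n")
                prev = areas[i]
            codes = " ".join(
                f"{a:0{width}d}{b:0{width}d}" for a, b in g.calls[i]
            )
            fh.write(f"{ind}, {codes}\n")
    if coords_path is not None:
        df = pd.DataFrame(
            {
                "individual": g.individuals,
                "x": g.coords[:, 0],
                "y": g.coords[:, 1],
                "area": g.area_tag or ["pop0"] * g.n,
            }
        )
        df.to_csv(coords_path, index=False)


# ---------------------------------------------------------------------------
# Distance metrics
# ---------------------------------------------------------------------------


def _shared_allele_count(call_a, call_b) -> int:
    """Alleles shared between two diploid calls, counting multiplicity (0-2)."""
    a = sorted(call_a)
    b = sorted(call_b)
    shared = 0
    bb = list(b)
    for x in a:
        if x in bb:
            shared += 1
            bb.remove(x)
    return shared


def dps_matrix(g: GenotypeTable) -> DistanceMatrix:
    """Dps(i,j) = 1 - (shared alleles) / (2 x co-typed loci), missing excluded."""
    n, L = g.n, g.n_loci
    miss = g.missing_mask()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cotyped = ~miss[i] & ~miss[j]
            Lij = int(cotyped.sum())
            if Lij == 0:
                raise GeneticsError(
                    f"pair ({g.individuals[i]}, {g.individuals[j]}) shares no co-typed locus"
                )
            shared = sum(
                _shared_allele_count(g.calls[i, l], g.calls[j, l])
                for l in range(L)
                if cotyped[l]
            )
            out[i, j] = out[j, i] = 1.0 - shared / (2.0 * Lij)
    return DistanceMatrix(list(g.individuals), out, "genetic_dps")


def rousset_a_matrix(g: GenotypeTable) -> DistanceMatrix:
    """Rousset's a between individuals, the F/(1-F) analogue.

    Per locus l, Qw_l is the dataset-average probability that the two gene
    copies within an individual are identical; Qb_l(i,j) averages identity
    over the four inter-individual gene comparisons.  The multilocus estimate
    is the ratio of sums a(i,j) = sum_l (Qw_l - Qb_l) / sum_l (1 - Qw_l) over
    loci co-typed for the pair.  Negative values are legitimate (pairs more
    similar than the within-individual baseline).
    """
    n, L = g.n, g.n_loci
    miss = g.missing_mask()
    qw = np.full(L, np.nan)
    for l in range(L):
        typed = ~miss[:, l]
        if typed.sum() == 0:
            continue
        hom = g.calls[typed, l, 0] == g.calls[typed, l, 1]
        qw[l] = hom.mean()
    if np.all(np.isnan(qw)) or np.nansum(1 - qw) <= 0:
        raise GeneticsError("no polymorphism: all loci monomorphic (or untyped)")
    out = np.zeros((n, n))
    for i in range(n):
        ai = g.calls[i]
        for j in range(i + 1, n):
            bj = g.calls[j]
            cotyped = ~miss[i] & ~miss[j] & ~np.isnan(qw)
            if not cotyped.any():
                raise GeneticsError(
                    f"pair ({g.individuals[i]}, {g.individuals[j]}) shares no co-typed locus"
                )
            num = 0.0
            den = 0.0
            for l in np.flatnonzero(cotyped):
                qb = np.mean(
                    [float(ai[l, x] == bj[l, y]) for x in (0, 1) for y in (0, 1)]
                )
                num += qw[l] - qb
                den += 1.0 - qw[l]
            if den <= 0:
                raise GeneticsError(
                    f"pair ({g.individuals[i]}, {g.individuals[j]}): no polymorphism at co-typed loci"
                )
            out[i, j] = out[j, i] = num / den
    return DistanceMatrix(list(g.individuals), out, "genetic_a")


def euclidean_matrix(g: GenotypeTable) -> DistanceMatrix:
    """Straight-line distance in meters between sampling locations."""
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(g.coords))
    return DistanceMatrix(list(g.individuals), d, "geographic")
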