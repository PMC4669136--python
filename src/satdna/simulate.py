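"""Synthetic tandem-array genomes and 454-like read libraries.

The generator plants every structural feature the downstream pipeline is meant
to recover: monomer length and AT content, per-copy divergence (optionally
column-heterogeneous, i.e. a conserved-column backbone plus variable columns),
dimeric higher-order-repeat (HOR) structure with two alternating monomer
classes, direct/inverted internal motifs, restriction sites intact in a
tunable fraction of copies, 454-like read lengths and substitution errors, and
a small male/female abundance differential.  A ground-truth table records every
emitted monomer so recovery can be scored exactly.

Mutation model
--------------
Each monomer copy is mutated independently: every *mutable* column substitutes
with probability ``q`` to one of the 3 alternative bases (uniform).  Two copies
then match at a mutable column with probability ``w(q) = (1-q)^2 + q^2/3``, and
at a column where the two HOR class consensuses differ with probability
``m(q) = 2q(1-q)/3 + 2q^2/9``.  These closed forms drive the calibration
helpers that map printed identity levels onto generator rates.

Column-heterogeneous divergence exists because a uniform per-site model cannot
jointly reproduce a high mean pairwise identity and a large fraction of columns
monomorphic across >100 sequences: with ~16% per-pair divergence spread over
all columns, essentially no column stays monomorphic in a 131-sequence sample.
Real satellite monomers concentrate variation in hotspot columns; the
``variable_fraction`` field emulates exactly that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from satdna.core import IUPAC_SETS, SeqRecord, reverse_complement

__all__ = [
    "MotifPlan",
    "SitePlan",
    "FamilySpec",
    "Family",
    "LibrarySpec",
    "Genome",
    "TruthTable",
    "calibrate_within_rate",
    "calibrate_hor",
    "expected_pairwise_identity",
    "make_consensus",
    "build_family",
    "simulate_array",
    "sample_monomers",
    "build_genome",
    "simulate_library",
    "pive40_like",
    "pive180_like",
    "study_library_specs",
]

BASES = "ACGT"
_BASE_TO_IDX = {b: i for i, b in enumerate(BASES)}


_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
_DEC = np.array([ord(b) for b in BASES], dtype=np.uint8)


def _to_arr(seq: str) -> np.ndarray:
    a = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (a < 0).any():
        raise ValueError("sequence contains characters outside ACGT")
    return a


def _to_str(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode()


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class MotifPlan:
    """A planted internal motif: ``copies`` occurrences of one core sequence.

    ``kind="direct"`` plants all copies in the same orientation;
    ``kind="inverted"`` plants the second copy as the reverse complement of the
    first (copies must be 2).  ``identity`` is the target pairwise identity
    between the first copy and each subsequent one (mutations are planted
    exactly, so the realized identity equals ``round`` of the target).
    """

    kind: str
    length: int
    copies: int = 2
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "inverted"):
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if self.kind == "inverted" and self.copies != 2:
            raise ValueError("inverted motifs support exactly 2 copies")
        if self.copies < 2:
            raise ValueError("a motif needs >= 2 copies")
        if not 0.0 < self.identity <= 1.0:
            raise ValueError("identity must be in (0, 1]")


@dataclass(frozen=True)
class SitePlan:
    """A restriction site planted in the consensus, intact in a fraction of
    emitted copies (the rest carry one disabling substitution)."""

    enzyme: str
    site: str
    intact_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.intact_fraction <= 1.0:
            raise ValueError("intact_fraction must be in [0, 1]")
        for c in self.site:
            if c.upper() not in IUPAC_SETS:
                raise ValueError(f"bad IUPAC character {c!r} in site")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic satellite family.

    ``within_class_divergence`` is the per-mutable-column substitution
    probability applied independently to every emitted copy;
    ``between_class_divergence`` the fraction of consensus columns at which the
    two HOR class consensuses differ (used when ``hor_order == 2``);
    ``variable_fraction`` the fraction of columns that are mutable at all
    (1.0 = uniform model).
    """

    name: str
    monomer_length: int
    at_target: float = 0.5
    motif_plan: tuple[MotifPlan, ...] = ()
    hor_order: int = 1
    between_class_divergence: float = 0.0
    within_class_divergence: float = 0.0
    variable_fraction: float = 1.0
    site_plan: tuple[SitePlan, ...] = ()
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.monomer_length < 10:
            raise ValueError("monomer_length must be >= 10")
        if self.hor_order not in (1, 2):
            raise ValueError("hor_order must be 1 or 2")
        for r in (self.between_class_divergence, self.within_class_divergence):
            if not 0.0 <= r < 1.0:
                raise ValueError("divergences must be in [0, 1)")
        if not 0.0 < self.variable_fraction <= 1.0:
            raise ValueError("variable_fraction must be in (0, 1]")
        for m in self.motif_plan:
            if m.length >= self.monomer_length:
                raise ValueError("motif longer than monomer")
        object.__setattr__(self, "motif_plan", tuple(self.motif_plan))
        object.__setattr__(self, "site_plan", tuple(self.site_plan))


@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library: label, size, read-length model, error rate and
    per-family target abundance (fraction of reads containing the family)."""

    label: str
    n_reads: int
    read_len_mean: float = 350.0
    read_len_sd: float = 100.0
    read_len_min: int = 50
    error_rate: float = 0.005
    abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if sum(self.abundance.values()) > 1.0 + 1e-9:
            raise ValueError("abundance targets sum > 1")


# ---------------------------------------------------------------------------
# calibration (closed forms for the substitution model)


def _w(q: float) -> float:
    return (1.0 - q) ** 2 + q * q / 3.0


def _m(q: float) -> float:
    return 2.0 * q * (1.0 - q) / 3.0 + 2.0 * q * q / 9.0


def _rate_for_match_prob(w: float) -> float:
    """Invert ``w(q) = (1-q)^2 + q^2/3`` for the smaller root q."""
    if not 1.0 / 3.0 <= w <= 1.0:
        raise ValueError("match probability out of range [1/3, 1]")
    disc = 4.0 - (16.0 / 3.0) * (1.0 - w)
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def calibrate_within_rate(target_identity: float,
                          variable_fraction: float = 1.0) -> float:
    """Per-mutable-column rate q giving a mean pairwise identity.

    Mean identity = (1 - vf) + vf * w(q), so w(q) = 1 - (1 - target)/vf.
    """
    w = 1.0 - (1.0 - target_identity) / variable_fraction
    return _rate_for_match_prob(w)


def calibrate_hor(within_identity: float, between_identity: float
                  ) -> tuple[float, float]:
    """(within rate q, between-class divergence d) for HOR identity targets.

    Between-class identity = (1-d) * w(q) + d * m(q) under the uniform model.
    """
    q = _rate_for_match_prob(within_identity)
    w, m = _w(q), _m(q)
    d = (w - between_identity) / (w - m)
    if not 0.0 <= d < 1.0:
        raise ValueError("between identity unattainable at this within identity")
    return q, d


def expected_pairwise_identity(q: float, variable_fraction: float = 1.0) -> float:
    """Expected identity between two independently mutated copies."""
    return (1.0 - variable_fraction) + variable_fraction * _w(q)


# ---------------------------------------------------------------------------
# consensus construction


def _sample_bases(n: int, at: float, rng: np.random.Generator) -> np.ndarray:
    """Random bases with *exact* composition: round(at*n) A/T bases.

    The printed AT contents are properties of a consensus, so the generator
    pins the composition exactly rather than sampling it binomially (a lone
    43-mer would otherwise carry ~7 pp of AT noise).
    """
    n_at = round(at * n)
    n_a = n_at // 2 + int(rng.integers(0, 2)) if n_at % 2 else n_at // 2
    n_gc = n - n_at
    n_c = n_gc // 2 + int(rng.integers(0, 2)) if n_gc % 2 else n_gc // 2
    arr = np.array([0] * n_a + [3] * (n_at - n_a)
                   + [1] * n_c + [2] * (n_gc - n_c), dtype=np.int8)
    rng.shuffle(arr)
    return arr


def _mutate_exact(arr: np.ndarray, k: int, rng: np.random.Generator,
                  positions: np.ndarray | None = None) -> np.ndarray:
    out = arr.copy()
    if k == 0:
        return out
    pool = np.arange(len(arr)) if positions is None else positions
    idx = rng.choice(pool, size=k, replace=False)
    out[idx] = (out[idx] + rng.integers(1, 4, size=k)) % 4
    return out


def _realize_site(site: str, at: float, rng: np.random.Generator) -> str:
    out = []
    for c in site.upper():
        opts = sorted(IUPAC_SETS[c])
        w = np.array([at / 2 if b in "AT" else (1 - at) / 2 for b in opts])
        out.append(rng.choice(opts, p=w / w.sum()))
    return "".join(out)


def _place_segments(length: int, sizes: list[int], rng: np.random.Generator,
                    max_tries: int = 2000) -> list[int]:
    """Non-overlapping random start positions for segments of given sizes."""
    for _ in range(max_tries):
        occupied: list[tuple[int, int]] = []
        starts: list[int] = []
        ok = True
        for sz in sizes:
            if sz > length:
                ok = False
                break
            for _try in range(50):
                s = int(rng.integers(0, length - sz + 1))
                if all(s + sz <= a or s >= b for a, b in occupied):
                    occupied.append((s, s + sz))
                    starts.append(s)
                    break
            else:
                ok = False
                break
        if ok:
            return starts
    total = sum(sizes)
    raise ValueError(
        f"cannot pack {len(sizes)} segments totalling {total} bp without "
        f"overlap into a {length} bp monomer"
    )


def make_consensus(spec: FamilySpec, seed: int
                   ) -> tuple[str, list[tuple[str, int, int]], list[tuple[str, int, str]]]:
    """Random consensus of the requested length/AT with planted motifs & sites.

    Returns ``(consensus, motif_coords, site_coords)`` where ``motif_coords``
    is a list of ``(kind, start, end)`` per planted copy (0-based half-open,
    copies of one plan listed consecutively) and ``site_coords`` a list of
    ``(enzyme, start, realized_site)``.
    """
    rng = np.random.default_rng(seed)
    L = spec.monomer_length
    backbone = _sample_bases(L, spec.at_target, rng)

    sizes: list[int] = []
    for m in spec.motif_plan:
        sizes.extend([m.length] * m.copies)
    site_seqs = [_realize_site(s.site, spec.at_target, rng) for s in spec.site_plan]
    sizes.extend(len(s) for s in site_seqs)
    starts = _place_segments(L, sizes, rng)

    motif_coords: list[tuple[str, int, int]] = []
    k = 0
    for m in spec.motif_plan:
        core = _sample_bases(m.length, spec.at_target, rng)
        n_mut = round((1.0 - m.identity) * m.length)
        for c in range(m.copies):
            copy = core if c == 0 else _mutate_exact(core, n_mut, rng)
            if m.kind == "inverted" and c == 1:
                copy = _to_arr(reverse_complement(_to_str(copy)))
            s = starts[k]
            backbone[s:s + m.length] = copy
            motif_coords.append((m.kind, s, s + m.length))
            k += 1

    site_coords: list[tuple[str, int, str]] = []
    for plan, sseq in zip(spec.site_plan, site_seqs):
        s = starts[k]
        backbone[s:s + len(sseq)] = _to_arr(sseq)
        site_coords.append((plan.enzyme, s, sseq))
        k += 1

    _scrub_spurious_sites(backbone, spec, site_coords, motif_coords, rng)
    _adjust_at(backbone, spec, site_coords, motif_coords, rng)
    return _to_str(backbone), motif_coords, site_coords


def _adjust_at(backbone: np.ndarray, spec: FamilySpec,
               site_coords: list[tuple[str, int, str]],
               motif_coords: list[tuple[str, int, int]],
               rng: np.random.Generator, max_tries: int = 500) -> None:
    """Nudge unprotected backbone positions until the AT count equals
    ``round(at_target * L)`` exactly (planting and site scrubbing shift the
    sampled composition by a few bases).  A flip that would create a new
    enzyme-site match is reverted."""
    from satdna.core import iupac_match

    protected = np.zeros(len(backbone), dtype=bool)
    for _, s, sseq in site_coords:
        protected[s:s + len(sseq)] = True
    for _, a, b in motif_coords:
        protected[a:b] = True

    def creates_site(pos: int) -> bool:
        L = len(backbone)
        planted = {s for _, s, _ in site_coords}
        for plan in spec.site_plan:
            site = plan.site.upper()
            m = len(site)
            text = _to_str(backbone) + _to_str(backbone[:m - 1])
            # windows covering pos, including across the circular junction
            for shift in (pos, pos + L):
                for i in range(shift - m + 1, shift + 1):
                    if 0 <= i < L and i not in planted \
                            and iupac_match(site, text[i:i + m]):
                        return True
        return False

    target = round(spec.at_target * len(backbone))
    for _ in range(max_tries):
        is_at = (backbone == 0) | (backbone == 3)
        have = int(is_at.sum())
        if have == target:
            return
        want_at = have < target
        pool = np.flatnonzero(~protected & (is_at != want_at))
        if len(pool) == 0:
            break
        pos = int(rng.choice(pool))
        old = backbone[pos]
        backbone[pos] = int(rng.choice([0, 3] if want_at else [1, 2]))
        if creates_site(pos):
            backbone[pos] = old
            protected[pos] = True  # leave this one alone
    raise ValueError("cannot reach the target AT composition")


def _scrub_spurious_sites(backbone: np.ndarray, spec: FamilySpec,
                          site_coords: list[tuple[str, int, str]],
                          motif_coords: list[tuple[str, int, int]],
                          rng: np.random.Generator,
                          max_rounds: int = 50) -> None:
    """Disrupt chance matches of planted enzyme sites in the backbone, so the
    only site per monomer is the planted one (a chance second conserved site
    would cut every copy and destroy the single-unit ladder).

    The monomer is scanned as a circle: in a tandem array the junction
    between consecutive copies can itself spell a site, which would be just
    as conserved as an internal one."""
    from satdna.core import iupac_match

    L = len(backbone)
    planted = {s for _, s, _ in site_coords}
    protected = np.zeros(L, dtype=bool)
    for _, s, sseq in site_coords:
        protected[s:s + len(sseq)] = True
    for _, a, b in motif_coords:
        protected[a:b] = True
    for _ in range(max_rounds):
        dirty = False
        for plan in spec.site_plan:
            site = plan.site.upper()
            m = len(site)
            text = _to_str(backbone) + _to_str(backbone[:m - 1])
            for i in range(L):
                if i in planted:
                    continue
                if not iupac_match(site, text[i:i + m]):
                    continue
                free = [j for j in range(m)
                        if not protected[(i + j) % L] and site[j] != "N"]
                pos = free[0] if free else next(
                    j for j in range(m) if site[j] != "N")
                bad = sorted(set(BASES) - IUPAC_SETS[site[pos]])
                backbone[(i + pos) % L] = _BASE_TO_IDX[
                    bad[int(rng.integers(0, len(bad)))]]
                dirty = True
                break  # re-derive the doubled text before continuing
        if not dirty:
            return


@dataclass
class Family:
    """A realized family: spec + consensus + planted annotation + class
    consensuses (two when dimeric HOR) + mutable-column mask."""

    spec: FamilySpec
    consensus: str
    class_consensuses: list[str]
    motif_coords: list[tuple[str, int, int]]
    site_coords: list[tuple[str, int, str]]
    mutable_mask: np.ndarray

    @property
    def name(self) -> str:
        return self.spec.name


def build_family(spec: FamilySpec, seed: int) -> Family:
    """Realize a :class:`FamilySpec`: consensus, HOR class consensuses and the
    mutable-column mask (conserved columns and planted sites never mutate)."""
    cons, motif_coords, site_coords = make_consensus(spec, seed)
    rng = np.random.default_rng((seed, 1))
    L = spec.monomer_length
    site_cols = np.zeros(L, dtype=bool)
    for _, s, sseq in site_coords:
        site_cols[s:s + len(sseq)] = True
    candidates = np.flatnonzero(~site_cols)
    # site columns whose copies get knocked out are de-facto variable, so
    # they consume part of the variable-column budget: the conserved
    # (monomorphic) fraction then comes out at 1 - variable_fraction exactly
    n_site_var = sum(len(sseq) for plan, (_, _, sseq)
                     in zip(spec.site_plan, site_coords)
                     if plan.intact_fraction < 1.0)
    n_var = min(max(round(spec.variable_fraction * L) - n_site_var, 0),
                len(candidates))
    var_idx = rng.choice(candidates, size=n_var, replace=False)
    mask = np.zeros(L, dtype=bool)
    mask[var_idx] = True

    classes = [cons]
    if spec.hor_order == 2:
        k = round(spec.between_class_divergence * L)
        arr = _to_arr(cons)
        idx = rng.choice(candidates, size=min(k, len(candidates)),
                         replace=False)
        # composition-preserving transversions (A<->T, C<->G): the two class
        # consensuses then differ at k sites but share the calibrated AT
        # content, so the mosaic family consensus keeps it too
        arr[idx] = 3 - arr[idx]
        classes.append(_to_str(arr))
    return Family(spec, cons, classes, motif_coords, site_coords, mask)


# ---------------------------------------------------------------------------
# arrays and monomer sampling


def _emit_copy(family: Family, cls: int, rng: np.random.Generator) -> str:
    spec = family.spec
    arr = _to_arr(family.class_consensuses[cls])
    mutable = np.flatnonzero(family.mutable_mask)
    hit = mutable[rng.random(len(mutable)) < spec.within_class_divergence]
    arr[hit] = (arr[hit] + rng.integers(1, 4, size=len(hit))) % 4
    # restriction-site knockout in (1 - intact_fraction) of copies
    for plan, (enz, s, sseq) in zip(spec.site_plan, family.site_coords):
        if rng.random() >= plan.intact_fraction:
            pos = int(rng.integers(0, len(sseq)))
            code = plan.site.upper()[pos]
            allowed = IUPAC_SETS[code]
            bad = sorted(set(BASES) - allowed) or sorted(set(BASES) - {sseq[pos]})
            arr[s + pos] = _BASE_TO_IDX[bad[int(rng.integers(0, len(bad)))]]
    # scrub site matches created by chance mutations: site presence in a copy
    # is controlled by intact_fraction alone
    if spec.site_plan:
        from satdna.core import iupac_match

        planted = {s for _, s, _ in family.site_coords}
        for plan in spec.site_plan:
            site = plan.site.upper()
            m = len(site)
            text = _to_str(arr)
            for i in range(len(text) - m + 1):
                if i in planted:
                    continue
                if iupac_match(site, text[i:i + m]):
                    # disrupt at a mutable column when possible: touching a
                    # conserved column would break its monomorphism
                    free = [j for j in range(m) if site[j] != "N"
                            and family.mutable_mask[i + j]] \
                        if i + m <= len(family.mutable_mask) else []
                    pos = free[0] if free else next(
                        j for j in range(m) if site[j] != "N")
                    bad = sorted(set(BASES) - IUPAC_SETS[site[pos]])
                    arr[i + pos] = _BASE_TO_IDX[
                        bad[int(rng.integers(0, len(bad)))]]
    seq = _to_str(arr)
    if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
        p = int(rng.integers(0, len(seq)))
        if rng.random() < 0.5 and len(seq) > 1:
            seq = seq[:p] + seq[p + 1:]
        else:
            seq = seq[:p] + BASES[int(rng.integers(0, 4))] + seq[p:]
    return seq


def simulate_array(family: Family, n_copies: int, seed: int
                   ) -> tuple[str, pd.DataFrame]:
    """Tandem array of ``n_copies`` mutated monomer copies.

    With ``hor_order == 2`` the two class consensuses are tiled alternately
    (class = copy index mod 2).  Returns the array sequence and a truth frame
    with one row per copy: ``start``, ``end`` (0-based half-open in array
    coordinates), ``class_idx``, ``copy_idx``.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    rows = []
    pos = 0
    for c in range(n_copies):
        cls = c % family.spec.hor_order
        m = _emit_copy(family, cls, rng)
        parts.append(m)
        rows.append((pos, pos + len(m), cls, c))
        pos += len(m)
    truth = pd.DataFrame(rows, columns=["start", "end", "class_idx", "copy_idx"])
    return "".join(parts), truth


def sample_monomers(family: Family, n: int, seed: int,
                    reads_of: int = 4) -> list[tuple[str, int, str, int]]:
    """Draw ``n`` monomer copies grouped into pseudo-reads of ``reads_of``
    consecutive copies (for tests needing read/ordinal structure without the
    full library simulation).  Returns ``(seq, class_idx, read_id, ordinal)``.
    """
    rng = np.random.default_rng(seed)
    out = []
    read = -1
    for i in range(n):
        ordinal = i % reads_of
        if ordinal == 0:
            read += 1
            phase = int(rng.integers(0, family.spec.hor_order))
        cls = (phase + ordinal) % family.spec.hor_order
        out.append((_emit_copy(family, cls, rng), cls, f"read{read}", ordinal))
    return out


def plant_fixed_difference(family: Family, column: int | None = None
                           ) -> tuple[Family, int]:
    """A variant family whose consensus differs at exactly one *conserved*
    column (default: the first conserved, unprotected column).

    Sampling one group from the original family and the other from the
    variant plants exactly one fixed diagnostic position between them: the
    column never mutates, so it is monomorphic within each group and differs
    between groups.
    """
    L = family.spec.monomer_length
    protected = np.zeros(L, dtype=bool)
    for _, s, sseq in family.site_coords:
        protected[s:s + len(sseq)] = True
    if column is None:
        candidates = np.flatnonzero(~family.mutable_mask & ~protected)
        if len(candidates) == 0:
            raise ValueError("family has no conserved unprotected column")
        column = int(candidates[0])
    elif family.mutable_mask[column]:
        raise ValueError(f"column {column} is mutable, not conserved")
    new_classes = []
    for cons in family.class_consensuses:
        arr = _to_arr(cons)
        arr[column] = (arr[column] + 2) % 4  # transversion, deterministic
        new_classes.append(_to_str(arr))
    variant = Family(family.spec, new_classes[0], new_classes,
                     list(family.motif_coords), list(family.site_coords),
                     family.mutable_mask.copy())
    return variant, column


# ---------------------------------------------------------------------------
# genomes and libraries


@dataclass
class Genome:
    """Arrays per family plus random background, with array-level truth."""

    arrays: dict[str, str]
    array_truth: dict[str, pd.DataFrame]
    background: str


def build_genome(families: list[Family], seed: int,
                 array_length_bp: int = 20_000,
                 background_bp: int = 50_000,
                 background_at: float = 0.5) -> Genome:
    """Genome with one array per family, each ~``array_length_bp`` long."""
    rng = np.random.default_rng((seed, 99))
    arrays: dict[str, str] = {}
    truths: dict[str, pd.DataFrame] = {}
    for i, fam in enumerate(families):
        n_copies = max(2, math.ceil(array_length_bp / fam.spec.monomer_length))
        arr, truth = simulate_array(fam, n_copies, seed=int(rng.integers(2 ** 31)))
        arrays[fam.name] = arr
        truths[fam.name] = truth
    background = _to_str(_sample_bases(background_bp, background_at, rng))
    return Genome(arrays, truths, background)


def _read_length(lib: LibrarySpec, rng: np.random.Generator) -> int:
    n = rng.normal(lib.read_len_mean, lib.read_len_sd)
    return max(lib.read_len_min, int(round(n)))


def simulate_library(genome: Genome, lib: LibrarySpec, seed: int
                     ) -> tuple[list[SeqRecord], "TruthTable"]:
    """Draw a 454-like read library from a genome.

    Each read comes from family ``f`` with probability ``lib.abundance[f]``
    (uniform start inside the array, either strand) or from background
    otherwise; per-base substitution errors at ``lib.error_rate``.  The truth
    table records, per read, its source and per overlapped monomer its
    boundaries in read coordinates, class and strand.
    """
    rng = np.random.default_rng(seed)
    fams = sorted(lib.abundance)
    probs = np.array([lib.abundance[f] for f in fams])
    cum = np.cumsum(probs)
    truth_arrays = {
        f: (t["start"].to_numpy(), t["end"].to_numpy(),
            t["class_idx"].to_numpy(), t["copy_idx"].to_numpy())
        for f, t in genome.array_truth.items()
    }

    reads: list[SeqRecord] = []
    read_rows = []
    mono_rows = []
    for i in range(lib.n_reads):
        rid = f"{lib.label}_{i:07d}"
        u = rng.random()
        fam_i = int(np.searchsorted(cum, u))
        family = fams[fam_i] if fam_i < len(fams) else "background"
        source = genome.arrays.get(family, genome.background)
        length = _read_length(lib, rng)
        truncated = False
        if length >= len(source):
            length = len(source)
            start = 0
            truncated = True
        else:
            start = int(rng.integers(0, len(source) - length + 1))
        seq = source[start:start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        if lib.error_rate > 0:
            arr = _to_arr(seq)
            hit = np.flatnonzero(rng.random(len(arr)) < lib.error_rate)
            arr[hit] = (arr[hit] + rng.integers(1, 4, size=len(hit))) % 4
            seq = _to_str(arr)
        reads.append(SeqRecord(id=rid, seq=seq, label=lib.label, source="sim"))
        read_rows.append((rid, lib.label, family, start, start + length,
                          strand, truncated))
        if family != "background":
            starts_a, ends_a, cls_a, copy_a = truth_arrays[family]
            lo = int(np.searchsorted(ends_a, start, side="right"))
            hi = int(np.searchsorted(starts_a, start + length, side="left"))
            for t in range(lo, hi):
                a = max(int(starts_a[t]), start) - start
                b = min(int(ends_a[t]), start + length) - start
                if strand == "-":
                    a, b = length - b, length - a
                complete = (starts_a[t] >= start) and (ends_a[t] <= start + length)
                mono_rows.append((rid, family, a, b, int(cls_a[t]),
                                  int(copy_a[t]), strand, complete))
    reads_df = pd.DataFrame(read_rows, columns=[
        "read_id", "library", "family", "src_start", "src_end", "strand",
        "truncated"])
    mono_df = pd.DataFrame(mono_rows, columns=[
        "read_id", "family", "start", "end", "class_idx", "copy_idx",
        "strand", "complete"])
    return reads, TruthTable(reads_df, mono_df)


@dataclass
class TruthTable:
    """Ground truth of a simulated library: per-read provenance and per-monomer
    boundaries (0-based half-open, read coordinates)."""

    reads: pd.DataFrame
    monomers: pd.DataFrame

    def to_tsv(self, reads_path: str, monomers_path: str) -> None:
        self.reads.to_csv(reads_path, sep="\t", index=False)
        self.monomers.to_csv(monomers_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# study conditions


def pive40_like() -> FamilySpec:
    """A 43 bp family with dimeric HOR structure and a 9 bp direct+inverted
    motif, divergences calibrated so that within-HOR-class identity is ~0.89
    and between-class identity ~0.685."""
    q, d = calibrate_hor(0.89, 0.685)
    return FamilySpec(
        name="PIVE40S",
        monomer_length=43,
        at_target=0.605,
        motif_plan=(MotifPlan("inverted", 9, 2, 1.0),),
        hor_order=2,
        within_class_divergence=q,
        between_class_divergence=d,
    )


def pive180_like() -> FamilySpec:
    """A 177 bp family (uniform-length emulation of a 176-178 bp monomer),
    column-heterogeneous divergence calibrated to a mean pairwise identity of
    ~0.839 with ~53.1% of columns monomorphic in a >100-sequence sample; a
    23 bp direct motif pair at ~69.6% identity, an 18 bp direct pair at ~67%,
    and a HinfI site (GANTC) intact in 70% of copies."""
    vf = 1.0 - 0.5311
    q = calibrate_within_rate(0.839, vf)
    return FamilySpec(
        name="PIVE180S",
        monomer_length=177,
        at_target=0.59,
        motif_plan=(MotifPlan("direct", 23, 2, 0.696),
                    MotifPlan("direct", 18, 2, 0.67)),
        hor_order=1,
        within_class_divergence=q,
        variable_fraction=vf,
        site_plan=(SitePlan("HinfI", "GANTC", 0.70),),
    )


def study_library_specs(scale: float = 1.0) -> tuple[LibrarySpec, LibrarySpec]:
    """Male/female library specs at the study's sizes and satellite abundances
    (male: 105,277 reads, 3.93% / 3.79%; female: 82,143 reads, 3.38% / 3.05%
    for the 43 bp and 177 bp families respectively), optionally scaled down."""
    male = LibrarySpec(
        label="male", n_reads=max(1, round(105_277 * scale)),
        abundance={"PIVE40S": 0.0393, "PIVE180S": 0.0379})
    female = LibrarySpec(
        label="female", n_reads=max(1, round(82_143 * scale)),
        abundance={"PIVE40S": 0.0338, "PIVE180S": 0.0305})
    return male, female
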