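"""Configurable synthetic diploid loci patterned on an aroma-gene promoter.

The generator emits promoter+gene haplotypes carrying a configurable subset
of the locus' structural variants:

* a 426-bp promoter element (right edge at -2164) containing a nested 26-bp
  element with the CBNAC repressor-binding motif TTGCTTA;
* a 42-bp element at -354..-313, sitting inside the 56-bp spacer between two
  TATAWAW consensus TATA boxes;
* a 3-kb promoter deletion removing nearly the whole upstream region;
* an exon-2 retroelement insertion flanked by a 5-bp target-site
  duplication — either a solo LTR (499 bp) or a full terminal-repeat
  retrotransposon in miniature (TRIM: 499-bp 5'LTR, 188-bp internal region,
  496-bp 3'LTR);
* whole-locus loss (no sequence emitted at all).

Every indel edge is built with a boundary direct repeat (default 6 bp) and a
nearby inverted repeat (default 5 bp) whose one arm lies inside the indel —
the replication-slippage signature the downstream signature module detects.
Alleles with the same background seed differ *only* by their configured
variants, so alignment-based callers can be checked against generator truth.

The module also simulates short reads (uniform coverage, optional
substitution errors), qPCR Ct tables under an additive two-allele expression
model, and metabolite (MA) panels with configurable expression concordance.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field

import numpy as np

from foxyloci.coords import coord_to_index, index_to_coord

# ---------------------------------------------------------------------------
# locus architecture (promoter coordinates, ATG 'A' = +1, no position 0)

PROMOTER_LEN = 3300
EXON1_LEN, INTRON_LEN, EXON2_LEN = 600, 300, 900

ELEMENT_426 = (-2589, -2164)   # 426 bp, right edge at -2164
ELEMENT_26 = (-2420, -2395)    # nested inside the 426-bp element
ELEMENT_42 = (-354, -313)      # 42 bp inside the TATA spacer
DEL_3KB = (-3150, -151)        # 3000 bp promoter deletion
TATA_REGION = (-400, -250)
TATA_BOX_UP = (-369, -363)     # stamped "TATATAA"
TATA_BOX_DOWN = (-306, -300)   # stamped "TATAAAT"

EXON2_INSERTION_OFFSET = 300   # bp into exon 2
TSD_LEN = 5
LTR5_LEN, INTERNAL_LEN, LTR3_LEN = 499, 188, 496

DEFAULT_DR_LEN = 6             # boundary direct repeat
DEFAULT_IR_LEN = 5             # inverted repeat arm

TTGCTTA = "TTGCTTA"            # CBNAC repressor-binding motif
TATAWAW = "TATAWAW"

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class ConfigurationError(ValueError):
    """Raised for contradictory haplotype flags."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class HaplotypeSpec:
    """Declarative description of one promoter+gene haplotype.

    ``seed`` controls the neutral background; two specs with the same seed
    share every base outside their configured variants.
    """

    name: str
    has_426: bool = True
    has_26_within_426: bool = True
    has_42: bool = True
    has_3kb_promoter: bool = True
    exon2_insertion: str = "none"     # none | soloLTR | fullTRIM
    locus_present: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.exon2_insertion not in ("none", "soloLTR", "fullTRIM"):
            raise ConfigurationError(
                f"exon2_insertion={self.exon2_insertion!r} is not one of "
                "none/soloLTR/fullTRIM"
            )
        if self.has_26_within_426 and not self.has_426:
            raise ConfigurationError(
                "has_26_within_426=True contradicts has_426=False: the 26-bp "
                "element is nested inside the 426-bp element"
            )


@dataclass
class Allele:
    """A realized haplotype sequence with named feature intervals.

    ``element_intervals`` maps feature names to inclusive promoter-coordinate
    intervals in *this allele's own* coordinate system (deleting an element
    shifts everything upstream of it toward the ATG).
    """

    spec: HaplotypeSpec
    sequence: str
    atg_index: int
    element_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    def element_sequence(self, name: str) -> str:
        lo, hi = self.element_intervals[name]
        return self.sequence[coord_to_index(lo, self.atg_index):
                             coord_to_index(hi, self.atg_index) + 1]

    def coord(self, index: int) -> int:
        return index_to_coord(index, self.atg_index)

    def index(self, coord: int) -> int:
        return coord_to_index(coord, self.atg_index)


@dataclass
class Diploid:
    accession: str
    allele_a: Allele
    allele_b: Allele

    def genotype_string(self, element: str) -> str:
        """Per-indel genotype in size/0/'-' notation (e.g. '0/426', '426/-')."""
        labels = {"el426": "426", "el26": "26", "el42": "42", "del3kb": "3kb"}
        size = labels[element]
        toks = []
        for al in (self.allele_a, self.allele_b):
            s = al.spec
            if not s.locus_present or not s.has_3kb_promoter:
                toks.append("-")
            elif element == "el426":
                if not s.has_426:
                    toks.append("0")
                else:
                    toks.append("426" if s.has_26_within_426 else "400")
            elif element == "el26":
                toks.append(size if (s.has_426 and s.has_26_within_426) else "0")
            elif element == "el42":
                toks.append(size if s.has_42 else "0")
            else:
                raise KeyError(element)
        order = {"0": 0, "-": 2}
        toks.sort(key=lambda t: order.get(t, 1))
        return "/".join(toks)


# ---------------------------------------------------------------------------
# master sequence construction


def _background(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xF0C5])
    # GC ~ 0.4
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n,
                      p=[0.3, 0.2, 0.2, 0.3])


def _stamp(seq: list[str], atg: int, interval: tuple[int, int], text: str):
    i = coord_to_index(interval[0], atg)
    assert len(text) == coord_to_index(interval[1], atg) + 1 - i
    seq[i:i + len(text)] = list(text)


def _constrained_6mer(rng: np.random.Generator) -> str:
    """6-mer starting with C/G and with >=2 C/G overall (keeps repeat copies
    from seeding spurious TATA matches across deletion junctions)."""
    while True:
        s = "".join(rng.choice(list("ACGT"), size=6))
        if s[0] in "CG" and sum(c in "CG" for c in s) >= 2 and "TATA" not in s:
            return s


@dataclass(frozen=True)
class _MasterLayout:
    """Index-space layout of the all-elements-present master sequence."""
    atg: int
    features: dict[str, tuple[int, int]]          # name -> [start, end) indices
    insertion_point: int                          # index just after the TSD


@functools.lru_cache(maxsize=32)
def _build_master(seed: int, dr_len: int, ir_len: int) -> tuple[str, _MasterLayout]:
    total = PROMOTER_LEN + EXON1_LEN + INTRON_LEN + EXON2_LEN
    atg = PROMOTER_LEN
    seq = [b.decode() for b in _background(seed, total)]
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5EED])

    seq[atg:atg + 3] = list("ATG")
    _stamp(seq, atg, TATA_BOX_UP, "TATATAA")
    _stamp(seq, atg, TATA_BOX_DOWN, "TATAAAT")

    elements = {
        "el426": ELEMENT_426,
        "el26": ELEMENT_26,
        "el42": ELEMENT_42,
        "del3kb": DEL_3KB,
    }
    idx = {name: (coord_to_index(lo, atg), coord_to_index(hi, atg) + 1)
           for name, (lo, hi) in elements.items()}

    protected: set[int] = set()
    for box in (TATA_BOX_UP, TATA_BOX_DOWN):
        protected.update(range(coord_to_index(box[0], atg),
                               coord_to_index(box[1], atg) + 1))

    # direct repeats: element's leading dr_len bases copied immediately 3'
    for name, (s, e) in idx.items():
        head = _constrained_6mer(rng)[:dr_len] if dr_len <= 6 else None
        if head is None:
            head = _constrained_6mer(rng) + "".join(rng.choice(list("ACGT"),
                                                               size=dr_len - 6))
        seq[s:s + dr_len] = list(head)
        seq[e:e + dr_len] = list(head)
        protected.update(range(s, s + dr_len))
        protected.update(range(e, e + dr_len))

    # inverted repeats: revcomp of the outside direct-repeat copy's leading
    # ir_len bases, stamped inside the element near its 3' boundary
    ir_inside_offset = {"el426": 15, "el26": 8, "el42": 15, "del3kb": 15}
    for name, (s, e) in idx.items():
        arm = "".join(seq[e:e + ir_len])
        off = ir_inside_offset[name]
        seq[e - off:e - off + ir_len] = list(revcomp(arm))
        protected.update(range(e - off, e - off + ir_len))

    # repressor motif inside the 26-bp element (clear of its direct repeat)
    s26 = idx["el26"][0]
    seq[s26 + 8:s26 + 8 + len(TTGCTTA)] = list(TTGCTTA)
    protected.update(range(s26 + 8, s26 + 8 + len(TTGCTTA)))

    def _guards() -> bool:
        changed = False
        for s, e in idx.values():
            # no 5' homology: keeps generated indels left-aligned as placed
            if seq[s - 1] == seq[e - 1]:
                seq[s - 1] = "C" if seq[e - 1] != "C" else "G"
                changed = True
            # direct repeat exactly dr_len: block 3' extension
            if seq[s + dr_len] == seq[e + dr_len]:
                seq[s + dr_len] = "C" if seq[e + dr_len] != "C" else "G"
                changed = True
        return changed

    tata_lo = coord_to_index(TATA_REGION[0], atg)
    tata_hi = coord_to_index(TATA_REGION[1], atg) + 1
    box_starts = {coord_to_index(TATA_BOX_UP[0], atg),
                  coord_to_index(TATA_BOX_DOWN[0], atg)}
    pat = re.compile("(?=TATA[AT]A[AT])")

    def _clean_tata() -> bool:
        changed = False
        region = "".join(seq[tata_lo:tata_hi])
        for m in pat.finditer(region):
            start = tata_lo + m.start()
            if start in box_starts:
                continue
            for p in range(start, start + 7):
                if p not in protected:
                    seq[p] = "C"
                    changed = True
                    break
        return changed

    # guards write only C/G (never create a TATA match); iterate to fixpoint
    for _ in range(10):
        a = _clean_tata()
        b = _guards()
        if not (a or b):
            break

    # exon-2 insertion site guards are applied against the TE ends below
    q = atg + EXON1_LEN + INTRON_LEN + EXON2_INSERTION_OFFSET

    features = dict(idx)
    features["tata_region"] = (tata_lo, tata_hi)
    features["tata_box_up"] = (coord_to_index(TATA_BOX_UP[0], atg),
                               coord_to_index(TATA_BOX_UP[1], atg) + 1)
    features["tata_box_down"] = (coord_to_index(TATA_BOX_DOWN[0], atg),
                                 coord_to_index(TATA_BOX_DOWN[1], atg) + 1)
    features["exon2"] = (atg + EXON1_LEN + INTRON_LEN, total)
    return "".join(seq), _MasterLayout(atg=atg, features=features,
                                       insertion_point=q)


@functools.lru_cache(maxsize=32)
def _te_sequences(seed: int) -> tuple[str, str, str]:
    """(ltr5, internal, ltr3); the 3'LTR is the 5'LTR minus three bases."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x7E7E])
    ltr5 = "".join(rng.choice(list("ACGT"), size=LTR5_LEN,
                              p=[0.3, 0.2, 0.2, 0.3]))
    internal = "".join(rng.choice(list("ACGT"), size=INTERNAL_LEN,
                                  p=[0.3, 0.2, 0.2, 0.3]))
    ltr3 = "".join(c for i, c in enumerate(ltr5) if i not in (120, 240, 360))
    assert len(ltr3) == LTR3_LEN
    return ltr5, internal, ltr3


# ---------------------------------------------------------------------------
# haplotype assembly


def build_promoter_haplotype(spec: HaplotypeSpec,
                             dr_len: int = DEFAULT_DR_LEN,
                             ir_len: int = DEFAULT_IR_LEN) -> Allele:
    """Realize a haplotype sequence from its declarative spec.

    Deterministic for a given (seed, dr_len, ir_len). Whole-locus-loss specs
    yield an empty sequence.
    """
    if not spec.locus_present:
        return Allele(spec=spec, sequence="", atg_index=0, element_intervals={})

    master, layout = _build_master(spec.seed, dr_len, ir_len)
    atg = layout.atg

    deletions: list[tuple[int, int]] = []
    if not spec.has_3kb_promoter:
        deletions.append(layout.features["del3kb"])
    else:
        if not spec.has_426:
            deletions.append(layout.features["el426"])
        elif not spec.has_26_within_426:
            deletions.append(layout.features["el26"])
        if not spec.has_42:
            deletions.append(layout.features["el42"])
    deletions.sort()

    # splice out deletions, tracking index shifts
    seq = master
    kept = []
    prev = 0
    for s, e in deletions:
        kept.append(seq[prev:s])
        prev = e
    kept.append(seq[prev:])
    new_seq = "".join(kept)

    def shift(i: int) -> int:
        d = 0
        for s, e in deletions:
            if i >= e:
                d += e - s
            elif i > s:
                raise ValueError("index inside a deleted interval")
        return i - d

    new_atg = shift(atg)

    # exon-2 insertion with 5-bp target-site duplication
    q = shift(layout.insertion_point)
    te = ""
    if spec.exon2_insertion != "none":
        ltr5, internal, ltr3 = _te_sequences(spec.seed)
        te = ltr5 if spec.exon2_insertion == "soloLTR" else ltr5 + internal + ltr3
        host_l = new_seq[q - TSD_LEN - 1]      # base 5' of the target site
        host_r = new_seq[q]                    # base 3' of the target site
        # pin the TSD length and insertion placement to exactly TSD_LEN
        if te[0] == host_r:
            te = ("C" if host_r != "C" else "G") + te[1:]
        if te[-1] == host_l:
            te = te[:-1] + ("C" if host_l != "C" else "G")
        tsd = new_seq[q - TSD_LEN:q]
        new_seq = new_seq[:q] + te + tsd + new_seq[q:]

    intervals: dict[str, tuple[int, int]] = {}

    def record(name: str, master_interval: tuple[int, int]):
        s, e = master_interval
        if any(ds <= s and e <= de for ds, de in deletions):
            return
        try:
            ns, ne = shift(s), shift(e)
        except ValueError:
            return
        if spec.exon2_insertion != "none":
            if ns >= q:
                ns += len(te) + TSD_LEN
            if ne > q:
                ne += len(te) + TSD_LEN
        intervals[name] = (index_to_coord(ns, new_atg),
                           index_to_coord(ne - 1, new_atg))

    for name in ("el426", "el26", "el42", "tata_region",
                 "tata_box_up", "tata_box_down", "exon2"):
        if name == "el26" and (not spec.has_426 or not spec.has_26_within_426):
            continue
        if name == "el426" and not spec.has_426:
            continue
        if name == "el42" and not spec.has_42:
            continue
        if not spec.has_3kb_promoter and name in ("el426", "el26", "el42",
                                                  "tata_region",
                                                  "tata_box_up",
                                                  "tata_box_down"):
            continue
        record(name, layout.features[name])

    if spec.exon2_insertion != "none":
        intervals["te"] = (index_to_coord(q, new_atg),
                           index_to_coord(q + len(te) - 1, new_atg))
        intervals["tsd"] = (index_to_coord(q + len(te), new_atg),
                            index_to_coord(q + len(te) + TSD_LEN - 1, new_atg))

    return Allele(spec=spec, sequence=new_seq, atg_index=new_atg,
                  element_intervals=intervals)


# canonical haplotype archetypes used throughout the test suite and docs:
# the element-bearing reference type, the nested-element-missing reference,
# the big-deletion type, the TATA-element-missing type, plus structural
# variants of the element-bearing type.
CANONICAL_TYPES = {
    "caco": dict(has_426=True, has_26_within_426=True, has_42=True),
    "pn40024": dict(has_426=True, has_26_within_426=False, has_42=True),
    "concord": dict(has_426=False, has_26_within_426=False, has_42=True),
    "alba": dict(has_426=True, has_26_within_426=True, has_42=False),
    "del3kb": dict(has_3kb_promoter=False),
    "semillon": dict(locus_present=False),
    "solo_ltr": dict(exon2_insertion="soloLTR"),
    "full_trim": dict(exon2_insertion="fullTRIM"),
}


def canonical_spec(kind: str, seed: int = 0, name: str | None = None) -> HaplotypeSpec:
    """A named archetype spec sharing one background seed with its peers."""
    flags = CANONICAL_TYPES[kind]
    return HaplotypeSpec(name=name or kind, seed=seed, **flags)


def build_diploid(accession: str, kind_a: str, kind_b: str,
                  seed: int = 0) -> Diploid:
    return Diploid(accession=accession,
                   allele_a=build_promoter_haplotype(canonical_spec(kind_a, seed, f"{accession}.a")),
                   allele_b=build_promoter_haplotype(canonical_spec(kind_b, seed, f"{accession}.b")))


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class SimRead:
    name: str
    sequence: str
    quality: str

    def to_fastq(self) -> str:
        return f"@{self.name}\n{self.sequence}\n+\n{self.quality}\n"


def simulate_reads(diploid: Diploid, coverage: float = 30.0,
                   read_len: int = 150, error_rate: float = 0.0,
                   seed: int = 0) -> list[SimRead]:
    """Uniform single-end reads from both alleles.

    Per-allele read counts are Poisson with mean coverage*len/read_len;
    half the reads (in expectation) are reverse-complemented. Read names
    carry accession|allele|start|strand labels for test oracles.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not (0 <= error_rate < 0.1):
        raise ValueError("error_rate must be in [0, 0.1)")
    if read_len < 50:
        raise ValueError("read_len must be >= 50")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xBEAD])
    reads: list[SimRead] = []
    qual = "I" * read_len
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for which, allele in (("a", diploid.allele_a), ("b", diploid.allele_b)):
        n = len(allele.sequence)
        if n == 0:
            continue
        if read_len > n:
            raise ValueError(
                f"read_len {read_len} exceeds allele {allele.spec.name} "
                f"length {n}")
        count = rng.poisson(coverage * n / read_len)
        starts = rng.integers(0, n - read_len + 1, size=count)
        flips = rng.random(count) < 0.5
        for i, (st, flip) in enumerate(zip(starts, flips)):
            s = allele.sequence[st:st + read_len]
            if error_rate > 0:
                arr = np.frombuffer(s.encode(), dtype="S1").copy()
                hits = np.nonzero(rng.random(read_len) < error_rate)[0]
                for h in hits:
                    choices = bases[bases != arr[h]]
                    arr[h] = rng.choice(choices)
                s = arr.tobytes().decode()
            strand = "-" if flip else "+"
            if flip:
                s = revcomp(s)
            reads.append(SimRead(
                name=f"{diploid.accession}|{which}|{int(st)}|{strand}|{i}",
                sequence=s, quality=qual))
    return reads


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.to_fastq())


def read_fastq(path) -> list[SimRead]:
    from Bio import SeqIO
    return [SimRead(rec.id, str(rec.seq),
                    "".join(chr(q + 33) for q in
                            rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(str(path), "fastq")]


def write_fasta(alleles: list[Allele], path) -> None:
    with open(path, "w") as fh:
        for al in alleles:
            fh.write(f">{al.spec.name}\n")
            for i in range(0, len(al.sequence), 70):
                fh.write(al.sequence[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# expression and metabolite simulation


@dataclass
class ExpressionEffectModel:
    """Additive two-allele expression model driving the Ct simulator.

    Each functional allele contributes one expression unit multiplied by the
    effects of its missing repressive elements; alleles with the locus lost,
    the promoter deleted, or an exonic insertion contribute zero. Folds are
    scaled so the baseline accession's two-allele sum equals 1.
    """

    baseline: str
    effect_426_absent: float = 7.0
    effect_42_absent: float = 15.0
    ct_noise_sd: float = 0.0
    replicates: int = 3
    reference_ct: float = 20.0
    delta_ct_base: float = 5.0
    undetected_ct: float = 40.0

    def __post_init__(self):
        if self.effect_426_absent <= 0 or self.effect_42_absent <= 0:
            raise ValueError("multiplicative effects must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def allele_contribution(self, spec: HaplotypeSpec) -> float:
        if not spec.locus_present or not spec.has_3kb_promoter:
            return 0.0
        if spec.exon2_insertion != "none":
            return 0.0          # exonic insertion silences the allele
        f = 1.0
        if not spec.has_426:
            f *= self.effect_426_absent
        if not spec.has_42:
            f *= self.effect_42_absent
        return f

    def diploid_sum(self, d: Diploid) -> float:
        return (self.allele_contribution(d.allele_a.spec)
                + self.allele_contribution(d.allele_b.spec))

    def expected_fold(self, d: Diploid, baseline_sum: float) -> float:
        return self.diploid_sum(d) / baseline_sum


def simulate_expression_panel(panel: list[Diploid],
                              model: ExpressionEffectModel,
                              seed: int = 0):
    """Per-accession, per-replicate Ct values for target and reference genes.

    With ct_noise_sd=0 the comparative ddCt method recovers the configured
    folds to machine precision.
    """
    import pandas as pd

    if not panel:
        raise ValueError("panel is empty")
    by_name = {d.accession: d for d in panel}
    if model.baseline not in by_name:
        raise ValueError(f"baseline accession {model.baseline!r} not in panel")
    base_sum = model.diploid_sum(by_name[model.baseline])
    if base_sum <= 0:
        raise ValueError("baseline accession has zero expected expression")

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xC7C7])
    rows = []
    for d in panel:
        fold = model.expected_fold(d, base_sum)
        for rep in range(1, model.replicates + 1):
            noise_r = rng.normal(0, model.ct_noise_sd) if model.ct_noise_sd else 0.0
            noise_t = rng.normal(0, model.ct_noise_sd) if model.ct_noise_sd else 0.0
            ct_ref = model.reference_ct + noise_r
            if fold > 0:
                ct_tgt = (model.reference_ct + model.delta_ct_base
                          - np.log2(fold) + noise_t)
                ct_tgt = min(ct_tgt, model.undetected_ct)
            else:
                ct_tgt = model.undetected_ct
            rows.append((d.accession, rep, "reference", ct_ref))
            rows.append((d.accession, rep, "target", ct_tgt))
    return pd.DataFrame(rows, columns=["accession", "replicate", "gene", "ct"])


@dataclass
class MAConcordanceModel:
    """Metabolite expectation as a monotone function of expression fold,
    with accession-level discordance flags (high expression, low MA)."""

    exponent: float = 1.0
    noise_sd: float = 0.0            # sd of log-normal multiplicative noise
    discordant: frozenset = frozenset()
    discordant_level: float = 0.5    # MA (in baseline units) for flagged accessions


def simulate_ma_panel(folds, model: MAConcordanceModel, seed: int = 0):
    """MA values per accession from an expression-fold table.

    ``folds``: DataFrame with columns accession, fold (baseline fold = 1).
    """
    import pandas as pd

    if (folds["fold"] < 0).any():
        raise ValueError("negative expression input")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x3A3A])
    rows = []
    for acc, fold in zip(folds["accession"], folds["fold"]):
        noise = np.exp(rng.normal(0, model.noise_sd)) if model.noise_sd else 1.0
        if acc in model.discordant:
            ma = model.discordant_level * noise
        else:
            ma = (fold ** model.exponent) * noise
        rows.append((acc, max(ma, 1e-9)))
    return pd.DataFrame(rows, columns=["accession", "ma"])
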