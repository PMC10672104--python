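"""Stochastic biopanning simulator with a complete ground-truth ledger.

The generative model mirrors one selection round of phage display against an
immobilised antigen:

1. *preheat survival* (condition H only): each phage survives the heat
   treatment with its clone's survival probability;
2. *binding bottleneck*: a clone's capture probability is its base affinity
   times the condition modifier (clamped to (0, 1]); the bound pool is a
   multinomial draw over clones weighted by count x capture probability,
   of size min(bound capacity, expected binders);
3. *amplification*: bound counts are multiplied by the clone's bacterial
   expression bias with per-clone log-normal noise, then renormalised to
   the next round's input size by a multinomial draw.

Sequencing draws reads from the final pool counts, back-translates each
clone's VNAR cassette with a fixed codon table, embeds it in constant
vector flanks, and injects substitution errors and 3' truncations.  Every
stochastic choice is recorded in a ledger, so each analysis stage can be
checked against planted truth.

Scales are desk-sized in compute (clone counts, never individual phage):
the default library holds 10^11 in-silico phage, two orders below a
bench-scale 10^13 input — large enough that a clone below the sequencing
detection limit still exists as hundreds of physical copies, so its
selection trajectory is not dominated by founder noise.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import _codec
from .pools import INPUT_POOL, PoolId

CONDITION_ORDER = ("N", "L", "S", "U", "H")
_MODIFIER_KEY = {"L": "low_temp", "S": "high_salt", "U": "high_urea"}

# --------------------------------------------------------------------------
# framework templates and flanking vector context
# --------------------------------------------------------------------------

#: Constant framework segments of the simulated topeshark framework.  The
#: canonical cysteines sit in FR1 (…TINC…) and at the FR3b terminus; the
#: FR2/FR4 variants carry the extra framework cysteines of type I domains.
#: These sequences match the default anchor patterns in `annotation`.
FR1 = "ARVDQTPQTITKETGESLTINCVLRD"
FR2 = "TYWYRKKSGSTNEESISKGG"
FR2_CYS = "TYWYRKCSGSTNEESISKGG"
FR3A = "KSFSLRINDLTV"
FR3B = "EDSGTYYC"
FR4 = "DGAGTAVTVN"
FR4_CYS = "DGAGTAVTVC"

#: Fixed vector context flanking the VNAR cassette in the amplicon; the 5'
#: flank length is a multiple of 3 so clean reads code in frame 0.
FLANK5 = (
    "CATGCCATGGCTAGCTCTAGACTCGAGGTTAACGAATTCAAGCTTGATATCGAATTCCTG"
)
FLANK3 = "GGTGGAGGCGGTTCAGGCGGAGGTGGCTCTGGCGGTGGCGGATCG"


@dataclass(frozen=True)
class FrameworkTemplate:
    """Everything of a VNAR protein except its CDR3."""

    template_id: str
    cdr1: str
    hv2: str
    hv4: str
    fr2: str = FR2
    fr4: str = FR4

    def protein(self, cdr3: str) -> str:
        return FR1 + self.cdr1 + self.fr2 + self.hv2 + FR3A + self.hv4 + FR3B + cdr3 + self.fr4


@dataclass(frozen=True)
class CloneSpec:
    """One clone of the library and its selection phenotype."""

    clone_id: str
    cdr3: str
    framework_id: str
    vnar_type: str
    base_affinity: float
    condition_modifiers: Mapping[str, float] = field(
        default_factory=lambda: {
            "low_temp": 1.0,
            "high_salt": 1.0,
            "high_urea": 1.0,
            "preheat_survival": 1.0,
        }
    )
    expression_bias: float = 1.0
    binding_active: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.base_affinity <= 1.0:
            raise ValueError(f"{self.clone_id}: base_affinity must be in (0, 1]")
        if any(v <= 0 for v in self.condition_modifiers.values()):
            raise ValueError(f"{self.clone_id}: condition modifiers must be > 0")
        if self.expression_bias <= 0:
            raise ValueError(f"{self.clone_id}: expression_bias must be > 0")

    def capture_probability(self, condition: str) -> float:
        """Clamped binding probability under one condition."""
        mod = self.condition_modifiers.get(_MODIFIER_KEY.get(condition, ""), 1.0)
        return float(np.clip(self.base_affinity * mod, 0.0, 1.0))


class EmptyPoolError(RuntimeError):
    """All capture probabilities (or counts) vanished during a round."""


@dataclass(eq=False)
class PanningScenario:
    """Full configuration of a simulated panning study."""

    clones: list[CloneSpec]
    initial_frequencies: np.ndarray
    frameworks: dict[str, FrameworkTemplate]
    input_phage_count: int = 100_000_000_000
    bound_capacity: int = 1_000_000_000
    rounds: int = 3
    conditions: tuple[str, ...] = CONDITION_ORDER
    error_rate: float = 3e-4
    short_read_fraction: float = 0.05
    amplification_sigma: float = 0.08
    activity_threshold: float = 0.05
    seed: int = 0
    planted: dict[str, str] = field(default_factory=dict)  # condition -> clone_id

    def __post_init__(self) -> None:
        self.initial_frequencies = np.asarray(self.initial_frequencies, dtype=float)
        if len(self.initial_frequencies) != len(self.clones):
            raise ValueError("initial_frequencies length mismatch")
        if not np.isclose(self.initial_frequencies.sum(), 1.0, atol=1e-9):
            raise ValueError("initial frequencies must sum to 1")
        if (self.initial_frequencies < 0).any():
            raise ValueError("initial frequencies must be non-negative")
        if self.input_phage_count <= 0 or self.bound_capacity <= 0:
            raise ValueError("pool sizes must be positive")
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("clone ids must be unique")
        cdr3s = [c.cdr3 for c in self.clones]
        if len(set(cdr3s)) != len(cdr3s):
            raise ValueError("clone CDR3s must be unique (CDR3 is the clone key)")
        for c in self.clones:
            if c.binding_active != (c.base_affinity >= self.activity_threshold):
                raise ValueError(
                    f"{c.clone_id}: binding_active inconsistent with affinity "
                    f"{c.base_affinity} vs threshold {self.activity_threshold}"
                )
        self._cache: dict = {}

    # ---- vectorised clone attributes -------------------------------------
    def _arr(self, key: str, build) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = build()
        return self._cache[key]

    @property
    def affinity(self) -> np.ndarray:
        return self._arr("aff", lambda: np.array([c.base_affinity for c in self.clones]))

    @property
    def bias(self) -> np.ndarray:
        return self._arr("bias", lambda: np.array([c.expression_bias for c in self.clones]))

    @property
    def survival(self) -> np.ndarray:
        return self._arr(
            "surv",
            lambda: np.clip(
                [c.condition_modifiers.get("preheat_survival", 1.0) for c in self.clones],
                0.0,
                1.0,
            ),
        )

    def capture(self, condition: str) -> np.ndarray:
        return self._arr(
            f"cap_{condition}",
            lambda: np.array([c.capture_probability(condition) for c in self.clones]),
        )

    def clone_protein(self, index: int) -> str:
        clone = self.clones[index]
        return self.frameworks[clone.framework_id].protein(clone.cdr3)

    def clone_read_codes(self, index: int) -> np.ndarray:
        """Error-free amplicon (flanks + back-translated CDS) as 0-3 codes."""
        key = f"tpl_{index}"
        if key not in self._cache:
            nt = FLANK5 + _codec.back_translate(self.clone_protein(index)) + FLANK3
            mat, _ = _codec.encode_reads([nt])
            self._cache[key] = mat[0]
        return self._cache[key]

    def binding_table(self) -> dict[str, bool]:
        return {c.cdr3: c.binding_active for c in self.clones}

    # ---- deterministic expectations (used for calibration and oracles) ---
    def expected_frequencies(self, condition: str, rounds: int | None = None) -> np.ndarray:
        """Noise-free frequency recursion through the panning rounds.

        Bottleneck caps and renormalisation scale all clones alike, so the
        expected frequency update per round is f ∝ f x survival x capture x
        bias (survival only under H).
        """
        f = self.initial_frequencies.copy()
        surv = self.survival if condition == "H" else 1.0
        for _ in range(rounds if rounds is not None else self.rounds):
            w = f * surv * self.capture(condition) * self.bias
            total = w.sum()
            if total <= 0:
                raise EmptyPoolError(f"expected pool vanished under condition {condition}")
            f = w / total
        return f

    def planted_expected_fold_change(self) -> dict[str, float]:
        """Expected round-3 abundance ratio (own condition vs N) per plant."""
        out = {}
        f_ref = self.expected_frequencies("N")
        index = {c.clone_id: i for i, c in enumerate(self.clones)}
        for cond, clone_id in self.planted.items():
            i = index[clone_id]
            out[cond] = float(self.expected_frequencies(cond)[i] / f_ref[i])
        return out


# --------------------------------------------------------------------------
# the stochastic rounds
# --------------------------------------------------------------------------

def simulate_round(
    pool_counts: np.ndarray,
    condition: str,
    scenario: PanningScenario,
    rng: np.random.Generator,
) -> np.ndarray:
    """One panning round: (preheat) -> binding bottleneck -> amplification."""
    counts = np.asarray(pool_counts, dtype=np.int64)
    if counts.sum() <= 0:
        raise EmptyPoolError("input pool is empty")
    if condition == "H":
        counts = rng.binomial(counts, scenario.survival)
    w = counts * scenario.capture(condition)
    total_w = w.sum()
    if total_w <= 0:
        raise EmptyPoolError(f"no phage can bind under condition {condition}")
    bound_size = int(min(scenario.bound_capacity, round(total_w)))
    bound = rng.multinomial(bound_size, w / total_w)
    amp = bound * scenario.bias * rng.lognormal(0.0, scenario.amplification_sigma, len(bound))
    amp_total = amp.sum()
    if amp_total <= 0:
        raise EmptyPoolError("amplification produced an empty pool")
    return rng.multinomial(scenario.input_phage_count, amp / amp_total)


# --------------------------------------------------------------------------
# sequencing / read emission
# --------------------------------------------------------------------------

@dataclass(eq=False)
class SimulatedReads:
    """Emitted reads of one pool plus their per-read provenance.

    Sequences are held as a packed nucleotide-code buffer (clone-grouped,
    with a shuffle permutation mapping to the emitted read order) and only
    rendered to letter strings on demand; ``code_matrix`` hands the packed
    form straight to the read-processing stage without a round trip
    through text.
    """

    pool: PoolId
    clone_indices: np.ndarray  # emitted order
    errors: dict[int, list[int]]  # emitted read index -> substituted positions
    _buf: np.ndarray  # grouped nucleotide codes
    _offsets: np.ndarray  # grouped read boundaries in _buf
    _final_len: np.ndarray  # grouped, post-truncation lengths
    _order: np.ndarray  # emitted read k = grouped read _order[k]

    def __len__(self) -> int:
        return len(self.clone_indices)

    @property
    def ids(self) -> list[str]:
        label = self.pool.label
        return [f"{label}:{k:06d}" for k in range(len(self))]

    @property
    def sequences(self) -> list[bytes]:
        cached = getattr(self, "_sequences", None)
        if cached is None:
            letters = _codec.decode_codes(self._buf)
            starts = self._offsets[:-1].tolist()
            ends = (self._offsets[:-1] + self._final_len).tolist()
            cached = [letters[starts[g] : ends[g]] for g in self._order.tolist()]
            self._sequences = cached
        return cached

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))

    def code_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Padded (reads x bases) code matrix in emitted order."""
        n = len(self)
        lens = self._final_len
        width = int(lens.max()) if n else 0
        grouped = np.full((n, width), 4, dtype=np.uint8)
        # clone-grouped rows share a stride, so fill run-wise
        full = np.diff(self._offsets)
        run_starts = np.concatenate([[0], np.flatnonzero(np.diff(full) != 0) + 1, [n]])
        for a, b in zip(run_starts[:-1], run_starts[1:]):
            stride = int(full[a])
            block = self._buf[self._offsets[a] : self._offsets[b]]
            grouped[a:b, :stride] = block.reshape(b - a, stride)
        # blank truncated tails
        for g in np.flatnonzero(lens < full):
            grouped[g, int(lens[g]) :] = 4
        return grouped[self._order], lens[self._order].astype(np.int64)

    def reads_per_clone(self, n_clones: int) -> np.ndarray:
        return np.bincount(self.clone_indices, minlength=n_clones)

    def write_fastq(self, path) -> None:
        with open(path, "wb") as fh:
            for rid, seq in zip(self.ids, self.sequences):
                fh.write(b"@%s\n%s\n+\n%s\n" % (rid.encode(), seq, b"I" * len(seq)))


def emit_reads(
    pool_counts: np.ndarray,
    scenario: PanningScenario,
    depth: int,
    rng: np.random.Generator,
    pool: PoolId,
) -> SimulatedReads:
    """Sample reads from a pool through the error-bearing sequencing channel.

    Reads are drawn clone-proportionally, shuffled, substituted at
    ``error_rate`` per base, and truncated to <= 400 nt with probability
    ``short_read_fraction``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = np.asarray(pool_counts, dtype=np.int64)
    total = counts.sum()
    if total <= 0:
        raise EmptyPoolError("cannot sequence an empty pool")
    per_clone = rng.multinomial(depth, counts / total)
    present = np.nonzero(per_clone)[0]
    grouped_clone = np.repeat(present, per_clone[present])
    perm = rng.permutation(depth)  # read order is shuffled clone-wise

    # clone-grouped template buffer (vectorised), sliced per read in
    # shuffled order afterwards
    templates = {int(i): scenario.clone_read_codes(int(i)) for i in present}
    tpl_len = {i: len(t) for i, t in templates.items()}
    buf = np.concatenate(
        [np.tile(templates[int(i)], int(per_clone[i])) for i in present]
    )
    lens = np.fromiter(
        (tpl_len[int(c)] for c in grouped_clone), dtype=np.int64, count=depth
    )
    offsets = np.concatenate([[0], np.cumsum(lens)])
    read_clone = grouped_clone[perm]

    # substitution errors: sampled positions (with replacement; collisions
    # are vanishingly rare at these rates), forced to a different base
    n_err = rng.binomial(int(offsets[-1]), scenario.error_rate)
    inv = np.empty(depth, dtype=np.int64)
    inv[perm] = np.arange(depth)  # grouped index -> emitted read index
    errors: dict[int, list[int]] = {}
    if n_err:
        pos = np.unique(rng.integers(0, int(offsets[-1]), n_err))
        buf[pos] = (buf[pos] + rng.integers(1, 4, len(pos)).astype(np.uint8)) % 4
        owners = np.searchsorted(offsets, pos, side="right") - 1
        for p, o in zip(pos, owners):
            errors.setdefault(int(inv[o]), []).append(int(p - offsets[o]))

    final_len = lens.copy()
    short = rng.random(depth) < scenario.short_read_fraction
    if short.any():
        final_len[short] = np.minimum(
            final_len[short], rng.integers(250, 401, int(short.sum()))
        )

    return SimulatedReads(pool, read_clone, errors, buf, offsets, final_len, perm)


# --------------------------------------------------------------------------
# whole-study orchestration and the ground-truth ledger
# --------------------------------------------------------------------------

@dataclass(eq=False)
class GroundTruthLedger:
    """Planted truth for every stage: pool counts, read provenance, specs."""

    scenario: PanningScenario
    pool_counts: dict[str, np.ndarray]  # pool label -> phage per clone
    reads: dict[str, SimulatedReads] = field(default_factory=dict)

    def reads_per_clone(self, label: str) -> np.ndarray:
        return self.reads[label].reads_per_clone(len(self.scenario.clones))

    def expected_cdr3_counts(self, label: str) -> dict[str, int]:
        """CDR3 counts the pipeline would report on a lossless channel."""
        per_clone = self.reads_per_clone(label)
        return {
            self.scenario.clones[i].cdr3: int(per_clone[i])
            for i in np.nonzero(per_clone)[0]
        }

    def to_json(self, path, include_reads: bool = True) -> None:
        payload = {
            "seed": self.scenario.seed,
            "clones": [
                {
                    "clone_id": c.clone_id,
                    "cdr3": c.cdr3,
                    "framework_id": c.framework_id,
                    "vnar_type": c.vnar_type,
                    "base_affinity": c.base_affinity,
                    "condition_modifiers": dict(c.condition_modifiers),
                    "expression_bias": c.expression_bias,
                    "binding_active": c.binding_active,
                    "initial_frequency": float(self.scenario.initial_frequencies[i]),
                }
                for i, c in enumerate(self.scenario.clones)
            ],
            "pool_counts": {k: v.tolist() for k, v in self.pool_counts.items()},
        }
        if include_reads:
            payload["reads"] = {
                label: {
                    "clone_ids": [
                        self.scenario.clones[i].clone_id for i in r.clone_indices
                    ],
                    "errors": {str(k): v for k, v in sorted(r.errors.items())},
                }
                for label, r in self.reads.items()
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def run_panning(scenario: PanningScenario) -> GroundTruthLedger:
    """Run all rounds of all conditions; deterministic given the seed."""
    rng_in = np.random.default_rng([scenario.seed, 100])
    input_counts = rng_in.multinomial(
        scenario.input_phage_count, scenario.initial_frequencies
    )
    pools = {"Input": input_counts}
    for ci, cond in enumerate(scenario.conditions):
        rng = np.random.default_rng([scenario.seed, 101, ci])
        counts = input_counts
        for rd in range(1, scenario.rounds + 1):
            counts = simulate_round(counts, cond, scenario, rng)
            pools[f"{cond}{rd}"] = counts
    return GroundTruthLedger(scenario, pools)


def sequence_pools(
    ledger: GroundTruthLedger,
    depth: int,
    pools: Sequence[PoolId] | None = None,
) -> None:
    """Emit reads for the requested pools into the ledger (in place)."""
    scenario = ledger.scenario
    if pools is None:
        pools = [INPUT_POOL] + [
            PoolId(c, r)
            for c in scenario.conditions
            for r in range(1, scenario.rounds + 1)
        ]
    for pool in pools:
        label = pool.label
        tag = 0 if label == "Input" else (CONDITION_ORDER.index(pool.condition) + 1)
        rng = np.random.default_rng([scenario.seed, 202, tag, pool.round])
        ledger.reads[label] = emit_reads(
            ledger.pool_counts[label], scenario, depth, rng, pool
        )


def write_study(ledger: GroundTruthLedger, outdir, include_read_ledger: bool = True):
    """Write FASTQs, manifest, binding table and ledger JSON to a directory."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, reads in ledger.reads.items():
        fq = out / f"{label}.fastq"
        reads.write_fastq(fq)
        pool = reads.pool
        rows.append((fq.name, pool.condition, pool.round))
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("file\tcondition\tround\n")
        for name, cond, rd in rows:
            fh.write(f"{name}\t{cond}\t{rd}\n")
    from .enrichment import write_binding_table

    write_binding_table(ledger.scenario.binding_table(), out / "binding.tsv")
    ledger.to_json(out / "ledger.json", include_reads=include_read_ledger)
    return out / "manifest.tsv"


# --------------------------------------------------------------------------
# the reference study scenario
# --------------------------------------------------------------------------

_AA_NO_CW = [a for a in _codec.AA_LETTERS if a not in "CW"]
_AA_NO_C = [a for a in _codec.AA_LETTERS if a != "C"]


def _random_cdr3(rng: np.random.Generator, n_cys: int, taken: set[str]) -> str:
    while True:
        length = int(rng.integers(8, 19))
        res = list(rng.choice(_AA_NO_C, size=length))
        if n_cys:
            pos = rng.choice(np.arange(1, length - 1), size=n_cys, replace=False)
            for p in sorted(int(x) for x in pos):
                res[p] = "C"
        cdr3 = "".join(res)
        if cdr3 not in taken:
            taken.add(cdr3)
            return cdr3


def _make_framework(rng: np.random.Generator, fid: str, vnar_type: str) -> FrameworkTemplate:
    cdr1 = list(rng.choice(_AA_NO_CW, size=8))
    fr2, fr4 = FR2, FR4
    if vnar_type in ("II", "III"):
        cdr1[2] = "C"
    if vnar_type == "I":
        fr2, fr4 = FR2_CYS, FR4_CYS
    hv2 = "".join(rng.choice(_AA_NO_CW, size=8))
    hv4 = "".join(rng.choice(_AA_NO_CW, size=5))
    return FrameworkTemplate(fid, "".join(cdr1), hv2, hv4, fr2=fr2, fr4=fr4)


#: CDR3 cysteine count that realises each planted type on these frameworks.
_TYPE_CDR3_CYS = {"I": 0, "II": 1, "IV": 0, "V": 2}


def reference_scenario(
    seed: int,
    n_background: int = 2000,
    target_abundance_pct: float = 0.018,
    reference_depth: int = 176_000,
) -> PanningScenario:
    """Build the reference study scenario: a long-tailed background library,
    one dominant generalist binder, and one clone specifically favoured per
    condition L/S/H, each calibrated to land at ``target_abundance_pct``
    CDR3 abundance in its own round-3 pool while staying below the
    sequencing detection limit in Input and in N3.  Urea (U) confers no
    clone-specific advantage.  ``reference_depth`` only documents the
    sequencing depth the calibration is aimed at; it does not bound the
    depth reads may later be drawn at.
    """
    rng = np.random.default_rng([seed, 7])
    taken: set[str] = set()
    clones: list[CloneSpec] = []
    frameworks: dict[str, FrameworkTemplate] = {}

    type_choices = np.array(["II", "IV", "V", "I"])
    type_probs = np.array([0.55, 0.20, 0.15, 0.10])
    # a modest set of shared frameworks per type keeps the library realistic
    per_type_templates: dict[str, list[str]] = {}
    for t in type_choices:
        fids = []
        for k in range(8):
            fid = f"fw-{t}-{k}"
            frameworks[fid] = _make_framework(rng, fid, t)
            fids.append(fid)
        per_type_templates[t] = fids

    def modifiers(low=1.0, salt=1.0, urea=1.0, surv=1.0):
        return {
            "low_temp": low,
            "high_salt": salt,
            "high_urea": urea,
            "preheat_survival": surv,
        }

    activity_threshold = 0.05
    bg_types = rng.choice(type_choices, size=n_background, p=type_probs)
    bg_affinity = np.clip(rng.beta(0.4, 40.0, n_background), 1e-4, 1.0)
    bg_bias = rng.lognormal(0.0, 0.8, n_background)
    bg_survival = rng.uniform(0.005, 0.06, n_background)
    bg_jitter = rng.lognormal(0.0, 0.1, (n_background, 3))
    for i in range(n_background):
        t = str(bg_types[i])
        clones.append(
            CloneSpec(
                clone_id=f"BG{i:04d}",
                cdr3=_random_cdr3(rng, _TYPE_CDR3_CYS[t], taken),
                framework_id=str(rng.choice(per_type_templates[t])),
                vnar_type=t,
                base_affinity=float(bg_affinity[i]),
                condition_modifiers=modifiers(
                    low=float(bg_jitter[i, 0]),
                    salt=float(bg_jitter[i, 1]),
                    urea=float(bg_jitter[i, 2]),
                    surv=float(bg_survival[i]),
                ),
                expression_bias=float(bg_bias[i]),
                binding_active=bool(bg_affinity[i] >= activity_threshold),
            )
        )

    # dominant generalist: strong binder, strong expressor, abundant in the
    # input — the clone conventional picking would find
    clones.append(
        CloneSpec(
            clone_id="Z11-like",
            cdr3=_random_cdr3(rng, 1, taken),
            framework_id=per_type_templates["II"][0],
            vnar_type="II",
            base_affinity=0.35,
            condition_modifiers=modifiers(surv=0.08),
            expression_bias=2.0,
            binding_active=True,
        )
    )

    # condition-specific plants: genuine binders whose advantage exists only
    # under their own selection pressure
    plant_specs = {
        "L": dict(mod=modifiers(low=16.0, surv=0.1), t="II", aff=0.06),
        "S": dict(mod=modifiers(salt=16.0, surv=0.1), t="II", aff=0.06),
        "H": dict(mod=modifiers(surv=0.9), t="V", aff=0.12),
    }
    planted = {}
    for cond, ps in plant_specs.items():
        cid = f"{cond}3-planted"
        planted[cond] = cid
        clones.append(
            CloneSpec(
                clone_id=cid,
                cdr3=_random_cdr3(rng, _TYPE_CDR3_CYS[str(ps["t"])], taken),
                framework_id=per_type_templates[str(ps["t"])][1],
                vnar_type=str(ps["t"]),
                base_affinity=float(ps["aff"]),
                condition_modifiers=dict(ps["mod"]),
                expression_bias=float(np.exp(0.8**2 / 2)),  # library-mean bias
                binding_active=True,
            )
        )

    # long-tailed background frequencies; named clones get placeholders that
    # the calibration pass below overwrites
    freqs = np.empty(len(clones))
    bg_mass = rng.dirichlet(np.full(n_background, 0.5))
    freqs[:n_background] = bg_mass
    freqs[n_background] = 5e-4  # Z11-like
    freqs[n_background + 1 :] = 1e-8
    freqs /= freqs.sum()

    scenario = PanningScenario(
        clones=clones,
        initial_frequencies=freqs,
        frameworks=frameworks,
        activity_threshold=activity_threshold,
        seed=seed,
        planted=planted,
    )

    # calibrate planted input frequencies so the expected round-3 abundance
    # in the clone's own pool hits the target (linear in f0, so two passes
    # converge)
    index = {c.clone_id: i for i, c in enumerate(clones)}
    target = target_abundance_pct / 100.0
    for _ in range(3):
        f = scenario.initial_frequencies.copy()
        for cond, cid in planted.items():
            i = index[cid]
            achieved = scenario.expected_frequencies(cond)[i]
            f[i] *= target / achieved
        f /= f.sum()
        scenario = replace_frequencies(scenario, f)
    return scenario


def replace_frequencies(
    scenario: PanningScenario, frequencies: np.ndarray
) -> PanningScenario:
    """A copy of the scenario with a new initial-frequency vector."""
    return PanningScenario(
        clones=scenario.clones,
        initial_frequencies=frequencies,
        frameworks=scenario.frameworks,
        input_phage_count=scenario.input_phage_count,
        bound_capacity=scenario.bound_capacity,
        rounds=scenario.rounds,
        conditions=scenario.conditions,
        error_rate=scenario.error_rate,
        short_read_fraction=scenario.short_read_fraction,
        amplification_sigma=scenario.amplification_sigma,
        activity_threshold=scenario.activity_threshold,
        seed=scenario.seed,
        planted=dict(scenario.planted),
    )


def neutralized(scenario: PanningScenario) -> PanningScenario:
    """Null variant: every condition modifier (and survival) forced to 1.

    Binding flags are kept as they are; with no clone-specific pressure the
    condition pools become statistical replicates of N."""
    clones = [
        replace(
            c,
            condition_modifiers={
                "low_temp": 1.0,
                "high_salt": 1.0,
                "high_urea": 1.0,
                "preheat_survival": 1.0,
            },
        )
        for c in scenario.clones
    ]
    return PanningScenario(
        clones=clones,
        initial_frequencies=scenario.initial_frequencies,
        frameworks=scenario.frameworks,
        input_phage_count=scenario.input_phage_count,
        bound_capacity=scenario.bound_capacity,
        rounds=scenario.rounds,
        conditions=scenario.conditions,
        error_rate=scenario.error_rate,
        short_read_fraction=scenario.short_read_fraction,
        amplification_sigma=scenario.amplification_sigma,
        activity_threshold=scenario.activity_threshold,
        seed=scenario.seed,
        planted={},
    )
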