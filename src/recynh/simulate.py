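"""Synthetic rec-Y2H/Y3H screens with planted ground truth.

The simulator reproduces the statistical structure the scoring chain is
built to handle:

* clone-abundance skew: per-clone abundances are log-normal with unit
  median and spread ``abundance_sigma`` (overrepresented clones);
* RS sampling: read pairs are multinomial draws with cell weights
  proportional to the product of bait and prey abundances (recombination is
  interaction-blind);
* RIS sampling: cell weights additionally multiplied by
  (background + strength * planted + alpha_bait), so true interactors are
  enriched, auto-activating baits elevate their whole row, and a uniform
  background models reporter leakage;
* read structure: each mate is the mode's constant adapter followed by a
  prefix of the target's 3'-end reference (for RNA baits, of the expected
  read-1 sequence through the cloning flank), with i.i.d. substitution
  errors at ``per_base_error``.

The default minimum simulated insert length is 25 nt: inserts that short or
longer are guaranteed to clear the mapper's 1e-8 E-value cut-off for
reference sets up to roughly a thousand ORFs, which keeps error-free
simulations exactly recoverable by the read-processing stage (see
:mod:`recynh.mapping` for why a 15 nt match cannot pass).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .library import LibraryEntry, Role, ThreePrimeReference, build_reference
from .mapping import AdapterSpec, expected_rna_read1
from .matrix import CountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedFastq",
    "default_benchmark_config",
    "simulate_truth",
    "simulate_counts",
    "simulate_replicates",
    "simulate_fastq",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated screen.

    ``interactions`` are (bait_id, prey_id, strength) triples and
    ``autoactivators`` (bait_id, alpha) pairs; ids follow the generated
    naming scheme (``BAIT000``/``PREY000``, or ``RNA000`` in Y3H mode).
    """

    n_baits: int = 20
    n_preys: int = 20
    orf_len_range: tuple[int, int] = (300, 900)
    rna_len_range: tuple[int, int] = (30, 80)
    abundance_sigma: float = 1.0
    interactions: tuple[tuple[str, str, float], ...] = ()
    autoactivators: tuple[tuple[str, float], ...] = ()
    background: float = 1.0
    reads_per_condition: int = 200_000
    read_len: int = 150
    per_base_error: float = 0.005
    min_insert_len: int = 25
    reference_window: int = 100
    mode: str = "Y2H"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("Y2H", "Y3H"):
            raise ValueError("mode must be 'Y2H' or 'Y3H'")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if not (0 <= self.per_base_error < 1):
            raise ValueError("per_base_error must be in [0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a flat key:value config (tab- or space-separated).

        Planted sets use colon-delimited triples/pairs, e.g.::

            n_baits  10
            interactions  BAIT001:PREY002:50,BAIT003:PREY000:50
            autoactivators  BAIT005:30
        """
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, value = line.split(None, 1)
            value = value.strip()
            if key in ("n_baits", "n_preys", "reads_per_condition", "read_len",
                       "min_insert_len", "reference_window", "seed"):
                kwargs[key] = int(value)
            elif key in ("abundance_sigma", "background", "per_base_error"):
                kwargs[key] = float(value)
            elif key in ("orf_len_range", "rna_len_range"):
                lo, hi = value.replace(",", " ").split()
                kwargs[key] = (int(lo), int(hi))
            elif key == "mode":
                kwargs[key] = value.upper()
            elif key == "interactions":
                kwargs[key] = tuple(
                    (b, p, float(s))
                    for b, p, s in (item.split(":") for item in value.split(","))
                )
            elif key == "autoactivators":
                kwargs[key] = tuple(
                    (b, float(a))
                    for b, a in (item.split(":") for item in value.split(","))
                )
            else:
                raise ValueError(f"unknown simulator config key {key!r}")
        return cls(**kwargs)

    @property
    def bait_role(self) -> Role:
        return Role.RNA_BAIT if self.mode == "Y3H" else Role.BAIT

    def adapter_spec(self) -> AdapterSpec:
        return AdapterSpec.y3h() if self.mode == "Y3H" else AdapterSpec.y2h()


def default_benchmark_config(seed: int = 0, mode: str = "Y2H") -> SimConfig:
    """The standard parameter-recovery scenario.

    A 20 x 20 screen with ten planted interactions at strength 50 over a
    unit background, two auto-activating baits at alpha = 30, log-normal
    abundance spread sigma = 1, and 200k read pairs per condition: strong,
    sparse true interactions over realistic clone skew, with auto-activator
    rows for the upper-quartile subtraction to remove. Planted pairs are
    drawn (deterministically from ``seed``) among non-auto-activating baits.
    """
    rng = np.random.default_rng(seed)
    bait_prefix = "RNA" if mode == "Y3H" else "BAIT"
    bait_ids = [f"{bait_prefix}{i:03d}" for i in range(20)]
    prey_ids = [f"PREY{j:03d}" for j in range(20)]
    auto = rng.choice(20, size=2, replace=False)
    autoactivators = tuple((bait_ids[i], 30.0) for i in sorted(auto))
    clean_baits = [b for i, b in enumerate(bait_ids) if i not in auto]
    cells = [(b, p) for b in clean_baits for p in prey_ids]
    chosen = rng.choice(len(cells), size=10, replace=False)
    interactions = tuple(
        (cells[i][0], cells[i][1], 50.0) for i in sorted(chosen)
    )
    return SimConfig(
        interactions=interactions,
        autoactivators=autoactivators,
        mode=mode,
        seed=seed,
    )


@dataclass
class SimTruth:
    """Planted ground truth behind a simulated screen."""

    bait_entries: list[LibraryEntry]
    prey_entries: list[LibraryEntry]
    bait_abundance: dict[str, float]
    prey_abundance: dict[str, float]
    rs_weights: np.ndarray  # expected sampling weights, not normalised
    ris_weights: np.ndarray
    interactions: tuple[tuple[str, str, float], ...]
    autoactivators: tuple[tuple[str, float], ...]

    @property
    def bait_ids(self) -> list[str]:
        return [e.id for e in self.bait_entries]

    @property
    def prey_ids(self) -> list[str]:
        return [e.id for e in self.prey_entries]

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(x, y) for x, y, _s in self.interactions}

    @property
    def autoactivator_ids(self) -> set[str]:
        return {x for x, _a in self.autoactivators}

    def bait_references(self, window: int = 100) -> list[ThreePrimeReference]:
        return build_reference(self.bait_entries, window)

    def prey_references(self, window: int = 100) -> list[ThreePrimeReference]:
        return build_reference(self.prey_entries, window)


def _random_sequences(
    rng: np.random.Generator,
    n: int,
    prefix: str,
    len_range: tuple[int, int],
    role: Role,
) -> list[LibraryEntry]:
    entries = []
    for i in range(n):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        seq = "".join(rng.choice(_BASES, size=length))
        entries.append(
            LibraryEntry(
                id=f"{prefix}{i:03d}",
                display_name=f"{prefix}{i:03d}",
                sequence=seq,
                role=role,
            )
        )
    return entries


def _enrichment_matrix(
    cfg: SimConfig, bait_ids: list[str], prey_ids: list[str]
) -> np.ndarray:
    """RIS enrichment factors: background + interactions + auto-activation."""
    enrichment = np.full((cfg.n_baits, cfg.n_preys), cfg.background, dtype=float)
    bait_pos = {b: i for i, b in enumerate(bait_ids)}
    prey_pos = {p: j for j, p in enumerate(prey_ids)}
    for bait, alpha in cfg.autoactivators:
        if alpha < 0:
            raise ValueError("auto-activation strength must be >= 0")
        enrichment[bait_pos[bait], :] += alpha
    for bait, prey, strength in cfg.interactions:
        if strength < 0:
            raise ValueError("interaction strength must be >= 0")
        enrichment[bait_pos[bait], prey_pos[prey]] += strength
    return enrichment


def _draw_abundances(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    # log-normal with unit median: exp(sigma * Z)
    a_x = np.exp(cfg.abundance_sigma * rng.standard_normal(cfg.n_baits))
    a_y = np.exp(cfg.abundance_sigma * rng.standard_normal(cfg.n_preys))
    return a_x, a_y


def simulate_truth(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Generate libraries, abundances and per-condition sampling weights."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    bait_prefix = "RNA" if cfg.mode == "Y3H" else "BAIT"
    bait_len = cfg.rna_len_range if cfg.mode == "Y3H" else cfg.orf_len_range
    baits = _random_sequences(rng, cfg.n_baits, bait_prefix, bait_len, cfg.bait_role)
    preys = _random_sequences(rng, cfg.n_preys, "PREY", cfg.orf_len_range, Role.PREY)
    bait_ids = [e.id for e in baits]
    prey_ids = [e.id for e in preys]

    a_x, a_y = _draw_abundances(cfg, rng)
    enrichment = _enrichment_matrix(cfg, bait_ids, prey_ids)
    abundance = np.outer(a_x, a_y)
    rs_weights = abundance
    ris_weights = abundance * enrichment
    return SimTruth(
        bait_entries=baits,
        prey_entries=preys,
        bait_abundance=dict(zip(bait_ids, a_x)),
        prey_abundance=dict(zip(prey_ids, a_y)),
        rs_weights=rs_weights,
        ris_weights=ris_weights,
        interactions=tuple(cfg.interactions),
        autoactivators=tuple(cfg.autoactivators),
    )


def _draw_counts(
    rng: np.random.Generator,
    weights: np.ndarray,
    n_reads: int,
    bait_ids: list[str],
    prey_ids: list[str],
    condition: str,
) -> CountMatrix:
    total = weights.sum()
    if total == 0:
        raise ValueError("all-zero sampling weight matrix")
    draws = rng.multinomial(n_reads, (weights / total).ravel())
    return CountMatrix(
        baits=bait_ids,
        preys=prey_ids,
        values=draws.reshape(weights.shape),
        condition=condition,
    )


def simulate_counts(
    cfg: SimConfig, seed: int | None = None
) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Multinomial usable-read counts for both conditions, plus the truth."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = simulate_truth(cfg, rng)
    n_rs = _draw_counts(
        rng, truth.rs_weights, cfg.reads_per_condition, truth.bait_ids, truth.prey_ids, "RS"
    )
    n_ris = _draw_counts(
        rng, truth.ris_weights, cfg.reads_per_condition, truth.bait_ids, truth.prey_ids, "RIS"
    )
    return n_rs, n_ris, truth


def simulate_replicates(
    cfg: SimConfig,
    n_replicates: int = 3,
    seed: int | None = None,
    resample_abundance: bool = True,
) -> tuple[SimTruth, list[tuple[CountMatrix, CountMatrix]]]:
    """Replicate screens over one library with one planted interaction set.

    Screen replicates start at the library-transformation stage, so each
    replicate's clone representation is an independent log-normal draw by
    default (``resample_abundance``); the library sequences and the planted
    interaction/auto-activator sets are shared. The returned truth carries
    the first replicate's abundances. Averaging such replicates is what
    rescues true pairs that fall into the noise bulk of a single replicate
    because of unlucky clone representation.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = simulate_truth(cfg, rng)
    enrichment = truth.ris_weights / truth.rs_weights
    replicates = []
    for k in range(n_replicates):
        if k == 0 or not resample_abundance:
            rs_weights, ris_weights = truth.rs_weights, truth.ris_weights
        else:
            a_x, a_y = _draw_abundances(cfg, rng)
            rs_weights = np.outer(a_x, a_y)
            ris_weights = rs_weights * enrichment
        n_rs = _draw_counts(
            rng, rs_weights, cfg.reads_per_condition,
            truth.bait_ids, truth.prey_ids, "RS",
        )
        n_ris = _draw_counts(
            rng, ris_weights, cfg.reads_per_condition,
            truth.bait_ids, truth.prey_ids, "RIS",
        )
        replicates.append((n_rs, n_ris))
    return truth, replicates


@dataclass
class SimulatedFastq:
    """Paths and ground truth of a simulated paired-end screen."""

    rs_r1: Path
    rs_r2: Path
    ris_r1: Path
    ris_r2: Path
    counts_rs: CountMatrix
    counts_ris: CountMatrix
    truth: SimTruth


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def _write_condition_fastq(
    rng: np.random.Generator,
    counts: CountMatrix,
    cfg: SimConfig,
    bait_templates: list[str],
    prey_templates: list[str],
    r1_path: Path,
    r2_path: Path,
    tag: str,
) -> None:
    spec = cfg.adapter_spec()
    with open(r1_path, "w") as h1, open(r2_path, "w") as h2:
        serial = 0
        for i in range(counts.shape[0]):
            for j in range(counts.shape[1]):
                for _ in range(int(counts.values[i, j])):
                    serial += 1
                    name = f"sim_{tag}_{serial:07d}"
                    for template, adapter, handle in (
                        (bait_templates[i], spec.read1_adapter, h1),
                        (prey_templates[j], spec.read2_adapter, h2),
                    ):
                        max_insert = min(
                            cfg.read_len - len(adapter), len(template)
                        )
                        lo = min(cfg.min_insert_len, max_insert)
                        insert_len = int(rng.integers(lo, max_insert + 1))
                        read = adapter + template[:insert_len]
                        read = _mutate(rng, read, cfg.per_base_error)
                        handle.write(
                            f"@{name}\n{read}\n+\n{'I' * len(read)}\n"
                        )


def simulate_fastq(
    cfg: SimConfig, out_dir: str | Path, seed: int | None = None
) -> SimulatedFastq:
    """Simulate paired FASTQ for both conditions (plus the exact counts).

    At ``per_base_error = 0`` running the read-processing stage on the
    output reproduces ``counts_rs``/``counts_ris`` exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = simulate_truth(cfg, rng)
    counts = {}
    for condition, weights in (("RS", truth.rs_weights), ("RIS", truth.ris_weights)):
        counts[condition] = _draw_counts(
            rng, weights, cfg.reads_per_condition,
            truth.bait_ids, truth.prey_ids, condition,
        )
    if cfg.mode == "Y3H":
        bait_templates = [expected_rna_read1(e) for e in truth.bait_entries]
    else:
        bait_templates = [
            r.ref_seq for r in truth.bait_references(cfg.reference_window)
        ]
    prey_templates = [
        r.ref_seq for r in truth.prey_references(cfg.reference_window)
    ]
    paths = {}
    for condition in ("RS", "RIS"):
        r1 = out_dir / f"{condition.lower()}_r1.fastq"
        r2 = out_dir / f"{condition.lower()}_r2.fastq"
        _write_condition_fastq(
            rng, counts[condition], cfg, bait_templates, prey_templates,
            r1, r2, condition.lower(),
        )
        paths[condition] = (r1, r2)
    return SimulatedFastq(
        rs_r1=paths["RS"][0],
        rs_r2=paths["RS"][1],
        ris_r1=paths["RIS"][0],
        ris_r2=paths["RIS"][1],
        counts_rs=counts["RS"],
        counts_ris=counts["RIS"],
        truth=truth,
    )
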