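"""End-to-end orchestration: map -> score -> evaluate -> network from a manifest.

A run manifest names the screening mode, the libraries, and per replicate
either raw paired FASTQ for both conditions or pre-computed count matrices
(so users with their own mapper can reuse the scoring chain). Stage outputs
are written with fixed filenames under the output directory together with a
line-oriented key:value run log; outputs are pure functions of the manifest
and its inputs, so re-running with identical inputs reproduces identical
files.

Manifest file format (tab-separated, one statement per line)::

    mode        y2h
    baits       baits.fasta
    preys       preys.fasta
    positives   reference_pairs.tsv        # optional
    cutoff      1.2                        # optional (else grid scan)
    grid        0.1:5.0:0.1                # optional
    seed        7
    replicate   rep1  rs_counts.tsv  ris_counts.tsv
    replicate   rep2  rs_r1.fq rs_r2.fq ris_r1.fq ris_r2.fq
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from . import __version__
from .evaluation import (
    complexity,
    cutoff_scan,
    detect_autoactivators,
    load_reference_pairs,
)
from .library import Role, build_reference, load_library
from .mapping import AdapterSpec, count_pairs
from .matrix import CountMatrix, ISMatrix
from .network import build_network, write_edges
from .scoring import score_screen

__all__ = ["ReplicateInput", "RunManifest", "RunResult", "run_pipeline"]


@dataclass(frozen=True)
class ReplicateInput:
    """One replicate: either count TSVs or paired FASTQ per condition."""

    name: str
    rs_counts: Path | None = None
    ris_counts: Path | None = None
    rs_fastq: tuple[Path, Path] | None = None
    ris_fastq: tuple[Path, Path] | None = None

    @property
    def from_counts(self) -> bool:
        return self.rs_counts is not None

    def paths(self) -> list[Path]:
        if self.from_counts:
            return [self.rs_counts, self.ris_counts]  # type: ignore[list-item]
        return [*self.rs_fastq, *self.ris_fastq]  # type: ignore[misc]


@dataclass
class RunManifest:
    mode: str  # "Y2H" or "Y3H"
    bait_fasta: Path
    prey_fasta: Path
    replicates: list[ReplicateInput]
    out_dir: Path
    positives: Path | None = None
    cutoff: float | None = None
    grid: tuple[float, float, float] = (0.1, 5.0, 0.1)
    seed: int = 0
    apply_noise_filter: bool = True
    log_space: bool = False
    max_offset: int = 10
    evalue_cutoff: float = 1e-8
    reference_window: int = 100

    def validate(self) -> None:
        if self.mode not in ("Y2H", "Y3H"):
            raise ValueError("mode must be 'Y2H' or 'Y3H'")
        if not self.replicates:
            raise ValueError("at least one replicate required")
        for path in (self.bait_fasta, self.prey_fasta, self.positives):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        for rep in self.replicates:
            if rep.from_counts == (rep.rs_fastq is not None):
                raise ValueError(
                    f"replicate {rep.name!r} must supply either count TSVs "
                    "or FASTQ pairs for both conditions"
                )
            for path in rep.paths():
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(
                        f"replicate {rep.name!r}: missing input {path}"
                    )

    @classmethod
    def from_file(cls, path: str | Path, out_dir: str | Path) -> "RunManifest":
        base = Path(path).parent
        fields: dict[str, str] = {}
        replicates: list[ReplicateInput] = []
        with open(path) as handle:
            for line in handle:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                tokens = line.split("\t")
                key = tokens[0].lower()
                if key == "replicate":
                    name, *paths = tokens[1:]
                    resolved = [base / p for p in paths]
                    if len(paths) == 2:
                        replicates.append(
                            ReplicateInput(
                                name=name,
                                rs_counts=resolved[0],
                                ris_counts=resolved[1],
                            )
                        )
                    elif len(paths) == 4:
                        replicates.append(
                            ReplicateInput(
                                name=name,
                                rs_fastq=(resolved[0], resolved[1]),
                                ris_fastq=(resolved[2], resolved[3]),
                            )
                        )
                    else:
                        raise ValueError(
                            f"replicate line needs 2 (counts) or 4 (FASTQ) "
                            f"paths, got {len(paths)}"
                        )
                else:
                    fields[key] = tokens[1]
        manifest = cls(
            mode=fields.get("mode", "y2h").upper(),
            bait_fasta=base / fields["baits"],
            prey_fasta=base / fields["preys"],
            replicates=replicates,
            out_dir=Path(out_dir),
            positives=(base / fields["positives"]) if "positives" in fields else None,
            cutoff=float(fields["cutoff"]) if "cutoff" in fields else None,
            seed=int(fields.get("seed", "0")),
        )
        if "grid" in fields:
            lo, hi, step = (float(v) for v in fields["grid"].split(":"))
            manifest.grid = (lo, hi, step)
        return manifest


@dataclass
class RunResult:
    out_dir: Path
    is_final: ISMatrix
    cutoff: float | None
    n_edges: int | None


def _log_lines(manifest: RunManifest) -> list[str]:
    lines = [
        f"recynh_version\t{__version__}",
        f"mode\t{manifest.mode}",
        f"seed\t{manifest.seed}",
        f"noise_filter\t{manifest.apply_noise_filter}",
        f"max_offset\t{manifest.max_offset}",
        f"evalue_cutoff\t{manifest.evalue_cutoff}",
        f"n_replicates\t{len(manifest.replicates)}",
    ]
    return lines


def run_pipeline(manifest: RunManifest) -> RunResult:
    """Execute map -> score -> evaluate -> network, writing fixed filenames.

    Stages whose inputs are absent are skipped (mapping when a replicate
    supplies count TSVs; evaluation when no reference positives are given;
    network when no cut-off is fixed or found). Any stage error aborts with
    the stage and replicate named.
    """
    manifest.validate()
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _log_lines(manifest)

    bait_role = Role.RNA_BAIT if manifest.mode == "Y3H" else Role.BAIT
    bait_entries = load_library(manifest.bait_fasta, bait_role)
    prey_entries = load_library(manifest.prey_fasta, Role.PREY)
    bait_refs = build_reference(bait_entries, manifest.reference_window)
    prey_refs = build_reference(prey_entries, manifest.reference_window)
    spec = AdapterSpec.y3h() if manifest.mode == "Y3H" else AdapterSpec.y2h()

    replicate_counts: list[tuple[CountMatrix, CountMatrix]] = []
    for rep in manifest.replicates:
        try:
            if rep.from_counts:
                n_rs = CountMatrix.from_tsv(rep.rs_counts, condition="RS")
                n_ris = CountMatrix.from_tsv(rep.ris_counts, condition="RIS")
            else:
                pairs = {}
                for condition, (r1, r2) in (
                    ("RS", rep.rs_fastq),
                    ("RIS", rep.ris_fastq),
                ):
                    matrix, stats = count_pairs(
                        r1,
                        r2,
                        spec,
                        bait_refs=None if manifest.mode == "Y3H" else bait_refs,
                        prey_refs=prey_refs,
                        rna_entries=bait_entries if manifest.mode == "Y3H" else None,
                        condition=condition,
                        max_offset=manifest.max_offset,
                        evalue_cutoff=manifest.evalue_cutoff,
                    )
                    matrix.to_tsv(out / f"counts_{rep.name}_{condition}.tsv")
                    stats.to_tsv(out / f"mapping_stats_{rep.name}_{condition}.tsv")
                    log.append(
                        f"usable_fraction_{rep.name}_{condition}\t"
                        f"{stats.usable_fraction:.6f}"
                    )
                    pairs[condition] = matrix
                n_rs, n_ris = pairs["RS"], pairs["RIS"]
            n_rs.require_same_labels(n_ris)
            replicate_counts.append((n_rs, n_ris))
        except Exception as exc:
            raise RuntimeError(
                f"stage=mapping replicate={rep.name}: {exc}"
            ) from exc

    try:
        rs_total = replicate_counts[0][0]
        if len(replicate_counts) > 1:
            summed = np.sum([rs.values for rs, _ in replicate_counts], axis=0)
            rs_total = CountMatrix(
                baits=rs_total.baits, preys=rs_total.preys,
                values=summed, condition="RS",
            )
        report = complexity(rs_total)
        log.append(f"sample_complexity\t{report.sample_complexity:.6f}")
        log.append(f"pair_complexity\t{report.pair_complexity:.6f}")

        ris_total = replicate_counts[0][1]
        if len(replicate_counts) > 1:
            summed = np.sum([ris.values for _, ris in replicate_counts], axis=0)
            ris_total = CountMatrix(
                baits=ris_total.baits, preys=ris_total.preys,
                values=summed, condition="RIS",
            )
        auto = detect_autoactivators(ris_total, rs_total)
        auto.to_dataframe().to_csv(out / "autoactivators.tsv", sep="\t")
        log.append(f"flagged_autoactivators\t{','.join(auto.flagged_baits) or '-'}")
    except Exception as exc:
        raise RuntimeError(f"stage=qc: {exc}") from exc

    try:
        is_final = score_screen(
            replicate_counts,
            seed=manifest.seed,
            apply_noise_filter=manifest.apply_noise_filter,
            log_space=manifest.log_space,
        )
        is_final.to_tsv(out / "is_final.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage=scoring: {exc}") from exc

    cutoff = manifest.cutoff
    if manifest.positives is not None:
        try:
            positives = load_reference_pairs(manifest.positives)
            lo, hi, step = manifest.grid
            grid = np.arange(lo, hi + step / 2, step)
            scan = cutoff_scan(is_final, positives, grid)
            scan.table.to_csv(out / "cutoff_scan.tsv", sep="\t", index=False)
            log.append(f"best_f1_cutoff\t{scan.best_f1_cutoff:.4f}")
            log.append(f"best_mcc_cutoff\t{scan.best_mcc_cutoff:.4f}")
            if cutoff is None:
                cutoff = scan.best_f1_cutoff
        except Exception as exc:
            raise RuntimeError(f"stage=evaluation: {exc}") from exc

    n_edges = None
    if cutoff is not None:
        try:
            edges = build_network(is_final, cutoff)
            write_edges(edges, out / "edges.tsv")
            n_edges = len(edges)
            log.append(f"cutoff\t{cutoff}")
            log.append(f"n_edges\t{n_edges}")
        except Exception as exc:
            raise RuntimeError(f"stage=network: {exc}") from exc

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return RunResult(out_dir=out, is_final=is_final, cutoff=cutoff, n_edges=n_edges)
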