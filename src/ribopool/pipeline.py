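"""Pipeline orchestration: simulate → process → tabulate → compare → network.

One YAML config drives all stages; all randomness flows from the single
config seed (per-accession pool seeds are derived from it by accession
order).  The run manifest records per-stage read counts and outputs so that
provenance is reconstructable; reruns with an identical config produce
byte-identical outputs and an identical manifest hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .catalog import (
    DiagnosticMatrix,
    RibotypeTable,
    aggregate_pool,
    build_ribotype_table,
    call_pool,
    load_diagnostic_matrix,
    percent_of_pool,
    shared_ribotypes,
    write_table_tsv,
    MAJOR_THRESHOLD,
    NOVEL_FAMILY_CUTOFF,
)
from .parsnet import (
    Haplotype,
    NetworkConfig,
    build_network,
    write_edge_tsv,
    write_graphml,
)
from .readproc import TrimParams, process_fastq, write_uniques_fasta, write_uniques_tsv
from .reference import ReferenceFrame, materialize_ribotype_sequence
from .synth import PoolSpec, simulate_pool, write_pool

log = logging.getLogger("ribopool")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class AccessionConfig:
    id: str
    species: str = ""
    genome: str = ""
    # either a simulation recipe ...
    simulate: Mapping[str, Any] | None = None
    # ... or existing FASTQ mates
    r1: str | None = None
    r2: str | None = None


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str
    accessions: tuple[AccessionConfig, ...]
    seed: int = 0
    trim: TrimParams = TrimParams()
    min_overlap: int = 20
    max_mismatch_fraction: float = 0.1
    major_threshold: int = MAJOR_THRESHOLD
    derivative_mode: bool = False
    novel_family_cutoff: int = NOVEL_FAMILY_CUTOFF
    network: NetworkConfig = NetworkConfig()
    matrix_path: str | None = None

    @staticmethod
    def from_dict(d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        accs = tuple(AccessionConfig(**a) for a in d.pop("accessions", []))
        trim = TrimParams(**d.pop("trim", {}))
        net = NetworkConfig(**d.pop("network", {}))
        return PipelineConfig(accessions=accs, trim=trim, network=net, **d)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict[str, Any]:
        def convert(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, Mapping):
                return {k: convert(v) for k, v in obj.items()}
            return obj
        return convert(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage(manifest: dict, name: str, **counts: Any) -> None:
    manifest["stages"].append({"stage": name, **counts})
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(
    config: PipelineConfig,
    frame: ReferenceFrame | None = None,
    matrix: DiagnosticMatrix | None = None,
    sequences: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[str, Any]:
    """Run all stages and return the run manifest.

    ``sequences`` optionally supplies, per accession id, the true ribotype
    sequences a simulation recipe refers to; accessions without a recipe
    read their FASTQ mates from disk instead.
    """
    frame = frame or ReferenceFrame()
    matrix = matrix or load_diagnostic_matrix(config.matrix_path)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
        "accessions": {},
        "outputs": [],
    }
    marker = out / ".partial"
    marker.write_text("run in progress\n")
    tables: list[RibotypeTable] = []
    all_states: dict[str, dict[int, str]] = {}
    support: dict[str, int] = {}
    try:
        for i, acc in enumerate(config.accessions):
            t0 = time.perf_counter()
            if acc.simulate is not None:
                spec = PoolSpec(
                    accession_id=acc.id,
                    seed=config.seed * 1000 + i,
                    **acc.simulate,
                )
                if sequences is not None and acc.id in sequences:
                    acc_seqs = sequences[acc.id]
                else:
                    # default: mixture names resolve to catalog ribotypes
                    try:
                        acc_seqs = {
                            name: materialize_ribotype_sequence(frame, matrix.rows[name])
                            for name in spec.mixture
                        }
                    except KeyError as exc:
                        raise PipelineError(
                            f"stage=simulate accession={acc.id}: "
                            f"mixture ribotype {exc} not in catalog and no "
                            "sequences supplied"
                        ) from exc
                paths = write_pool(simulate_pool(spec, acc_seqs), out, acc.id)
                r1, r2 = paths["r1"], paths["r2"]
                _stage(manifest, "simulate", accession=acc.id, n_pairs=spec.n_read_pairs)
            else:
                if not acc.r1 or not acc.r2:
                    raise PipelineError(
                        f"stage=input accession={acc.id}: needs simulate block or r1/r2"
                    )
                r1, r2 = Path(acc.r1), Path(acc.r2)
                for p in (r1, r2):
                    if not p.exists():
                        raise PipelineError(
                            f"stage=input accession={acc.id}: missing FASTQ {p}"
                        )
            try:
                uniques, stats = process_fastq(
                    r1, r2, config.trim, config.min_overlap, config.max_mismatch_fraction
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage=process accession={acc.id}: {exc}") from exc
            _stage(
                manifest,
                "process",
                accession=acc.id,
                n_pairs=stats.n_pairs,
                n_discarded=stats.n_discarded,
                n_rejected=stats.n_rejected,
                n_merged=stats.n_merged,
                n_ambiguous=stats.n_ambiguous,
                n_unique=len(uniques),
                elapsed_s=None,
            )
            write_uniques_fasta(uniques, out / f"{acc.id}_uniques.fasta")
            write_uniques_tsv(uniques, out / f"{acc.id}_uniques.tsv")
            called, n_foreign = call_pool(
                uniques, frame, matrix, config.novel_family_cutoff
            )
            counts, states_by_name = aggregate_pool(
                called, matrix, derivative_mode=config.derivative_mode
            )
            table = build_ribotype_table(
                counts,
                accession_id=acc.id,
                total_reads=stats.n_merged,
                genome_label=acc.genome,
                major_threshold=config.major_threshold,
            )
            tables.append(table)
            write_table_tsv(table, out / f"{acc.id}_table.tsv")
            _stage(
                manifest,
                "tabulate",
                accession=acc.id,
                n_foreign=n_foreign,
                n_entries=len(table.entries),
                n_major=len(table.major_names()),
            )
            # pool network inputs across accessions; per-accession novel
            # labels are prefixed so they stay distinct
            for e in table.entries:
                if e.name in matrix.rows:
                    name, states = e.name, matrix.states_of(e.name)
                elif e.name in states_by_name:
                    name, states = f"{acc.id}:{e.name}", states_by_name[e.name]
                else:
                    continue
                support[name] = support.get(name, 0) + e.read_count
                all_states[name] = states
            manifest["accessions"][acc.id] = {
                "n_pairs": stats.n_pairs,
                "n_merged": stats.n_merged,
                "n_foreign": n_foreign,
                "major": sorted(table.major_names()),
            }
            log.info(
                "accession=%s done elapsed=%.1fs", acc.id, time.perf_counter() - t0
            )
        # cross-accession comparison
        comparisons = []
        for i, ta in enumerate(tables):
            for tb in tables[i + 1 :]:
                shared = shared_ribotypes(ta, tb)
                comparisons.append(
                    {
                        "a": ta.accession_id,
                        "b": tb.accession_id,
                        "shared": [s[0] for s in shared],
                        "overlap_score": sum(min(s[2], s[4]) for s in shared),
                    }
                )
        with open(out / "comparisons.json", "w") as fh:
            json.dump(comparisons, fh, indent=2, sort_keys=True)
        _stage(manifest, "compare", n_pairs_compared=len(comparisons))
        # network over all pools
        weights: dict[str, dict[str, int]] = {}
        for table in tables:
            for e in table.entries:
                key = e.name if e.name in matrix.rows else f"{table.accession_id}:{e.name}"
                if key in all_states and e.is_major:
                    weights.setdefault(key, {})[table.accession_id] = e.percent
        haplotypes = [
            Haplotype(
                name=n,
                states=all_states[n],
                total_reads=support[n],
                weights=weights.get(n, {}),
            )
            for n in sorted(all_states)
        ]
        network = build_network(
            haplotypes, config.network, sequence_length=len(frame)
        )
        write_graphml(network, out / "network.graphml")
        write_edge_tsv(network, out / "network_edges.tsv")
        n_components = len(
            {d["component"] for _, d in network.nodes(data=True)}
        ) if network.number_of_nodes() else 0
        _stage(
            manifest,
            "network",
            n_nodes=network.number_of_nodes(),
            n_edges=network.number_of_edges(),
            n_components=n_components,
            connection_limit=network.graph.get("connection_limit"),
        )
    except PipelineError:
        raise  # partial outputs retained; .partial marker stays
    # strip non-deterministic fields before hashing
    for s in manifest["stages"]:
        s.pop("elapsed_s", None)
    manifest["outputs"] = sorted(
        str(p.relative_to(out)) for p in out.iterdir() if p.name != ".partial"
    )
    # hash covers results, not filesystem locations: the config block holds
    # paths, so it is excluded
    hashable = {k: v for k, v in manifest.items() if k != "config"}
    blob = json.dumps(hashable, sort_keys=True).encode()
    manifest["manifest_sha256"] = hashlib.sha256(blob).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    marker.unlink(missing_ok=True)
    return manifest


# ---------------------------------------------------------------------------
# Table lint
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LintFinding:
    accession: str
    ribotype: str
    kind: str      # "percent-mismatch" | "sum-exceeds-total" | "major-flag"
    detail: str


def validate_table(table: RibotypeTable, major_threshold: int = MAJOR_THRESHOLD) -> list[LintFinding]:
    """Arithmetic lint for a ribotype table: printed percent vs recomputed
    round-half-up percent, entry counts summing above the pool total, and
    major flags inconsistent with the threshold."""
    findings: list[LintFinding] = []
    for e in table.entries:
        recomputed = percent_of_pool(e.read_count, table.total_reads)
        if recomputed != e.percent:
            findings.append(
                LintFinding(
                    table.accession_id,
                    e.name,
                    "percent-mismatch",
                    f"printed {e.percent}%, recomputed {recomputed}% "
                    f"({e.read_count}/{table.total_reads})",
                )
            )
        should_be_major = e.read_count > major_threshold
        if e.is_major != should_be_major:
            findings.append(
                LintFinding(
                    table.accession_id,
                    e.name,
                    "major-flag",
                    f"flag {e.is_major} but count {e.read_count} vs threshold {major_threshold}",
                )
            )
    total_counted = sum(e.read_count for e in table.entries)
    if total_counted > table.total_reads:
        findings.append(
            LintFinding(
                table.accession_id,
                "*",
                "sum-exceeds-total",
                f"entries sum to {total_counted} > total {table.total_reads}",
            )
        )
    return findings
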