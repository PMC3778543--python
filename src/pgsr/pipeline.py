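"""Run configuration and the end-to-end pipeline.

The pipeline chains signature computation, the driver-correlation screen
and functional binning, with optional phylogram and viral-enterotype
stages.  Every threshold is echoed into a machine-readable provenance
sidecar, and all randomness flows from the single configured seed, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .enterotypes import anosim, bray_curtis, heuristic_group, nmds
from .io import read_fasta, read_gff3, write_fasta, write_gff3, write_newick, write_signature_table, write_abundance_matrix
from .phylogeny import bootstrap_support
from .screening import DriverSet, bin_contig, screen_contigs
from .signatures import signature
from . import simulate as sim

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "contigs", "drivers", "annotations", "out_dir", "seed",
    "r_min", "min_len", "bootstrap_reps", "run_phylo",
    "run_enterotypes", "noise_incidence", "tau", "n_permutations",
    "log_level",
}


@dataclass
class RunConfig:
    """All pipeline thresholds, with the canonical defaults."""

    out_dir: str
    seed: int
    contigs: str | None = None
    drivers: str | None = None
    annotations: str | None = None
    r_min: float = 0.6
    min_len: int = 10_000
    bootstrap_reps: int = 200
    run_phylo: bool = False
    run_enterotypes: bool = False
    noise_incidence: float = 40.0
    tau: float = 0.6
    n_permutations: int = 999
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.r_min <= 1.0:
            raise ValueError(f"r_min must be in (0, 1], got {self.r_min}")
        if self.min_len < 1:
            raise ValueError("min_len must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if (self.contigs is None) != (self.drivers is None):
            raise ValueError("provide both contigs and drivers, or neither (synthetic run)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = set(mapping) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**mapping)


def run_pipeline(config: RunConfig) -> Path:
    """Execute signature -> screen -> bin (-> phylo -> enterotypes).

    Returns the run directory.  Inputs default to the shipped synthetic
    community when no FASTA paths are configured.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        rng = np.random.default_rng(config.seed)
        if config.contigs is None:
            stage = "simulate"
            community = sim.make_community(seed=config.seed)
            contigs = community.contigs
            drivers = DriverSet.from_sequences(
                list(community.drivers.values()), community.driver_host,
                min_len=config.min_len,
            )
            fixtures = sim.make_fixture_tables(community, seed=config.seed)
            orfs_by_contig = fixtures["orfs"]
            write_fasta(contigs, out / "contigs.fasta")
            write_fasta(list(community.drivers.values()), out / "drivers.fasta")
            write_gff3(
                [o for orfs in orfs_by_contig.values() for o in orfs],
                out / "annotations.gff3",
            )
            (out / "truth.json").write_text(
                json.dumps(community.truth, indent=2, sort_keys=True)
            )
        else:
            contigs = read_fasta(config.contigs)
            drivers = DriverSet.from_sequences(
                read_fasta(config.drivers), min_len=config.min_len
            )
            orfs_by_contig = {}
            if config.annotations:
                all_orfs = read_gff3(config.annotations)
                for o in all_orfs:
                    orfs_by_contig.setdefault(o.contig_id, []).append(o)

        stage = "signature"
        retained = [c for c in contigs if len(c) >= config.min_len]
        sigs = [signature(c) for c in retained]
        write_signature_table(sigs, out / "signatures.tsv")

        stage = "screen"
        hits = screen_contigs(contigs, drivers, config.r_min, config.min_len)

        stage = "bin"
        rows = []
        counts = {"phage": 0, "non_phage": 0, "unclassified": 0, "not_passed": 0}
        for h in hits:
            if h.passed and orfs_by_contig:
                fb = bin_contig(h.contig_id, orfs_by_contig.get(h.contig_id, []))
                category, rationale = fb.category, fb.rationale
            elif h.passed:
                category, rationale = "unclassified", "no annotations supplied"
            else:
                category, rationale = "", ""
            counts["not_passed" if not h.passed else category] += 1
            rows.append(
                f"{h.contig_id}\t{h.best_driver_id}\t{h.r_best:.10g}"
                f"\t{str(h.passed).lower()}\t{category}\t{rationale}"
            )
        (out / "screen.tsv").write_text(
            "contig_id\tbest_driver_id\tr_best\tpassed\tcategory\trationale\n"
            + "".join(r + "\n" for r in rows)
        )

        stages_run = ["signature", "screen", "bin"]
        if config.run_phylo:
            stage = "phylo"
            tree_sigs = [d.signature for d in drivers] + [
                s for s, h in zip(sigs, hits) if h.passed
            ]
            # re-pair signatures with screen order
            sig_by_id = {s.sequence_id: s for s in sigs}
            tree_sigs = [d.signature for d in drivers] + [
                sig_by_id[h.contig_id] for h in hits if h.passed
            ]
            if len(tree_sigs) >= 3:
                tree = bootstrap_support(
                    tree_sigs, n_reps=config.bootstrap_reps,
                    seed=int(rng.integers(2**31)),
                )
                write_newick(tree, out / "tree.nwk")
                stages_run.append("phylo")

        if config.run_enterotypes:
            stage = "enterotypes"
            matrix, truth_labels = sim.make_enterotype_cohort(seed=config.seed)
            write_abundance_matrix(matrix, out / "abundance.tsv")
            assign = heuristic_group(
                matrix, config.noise_incidence, config.tau,
                seed=int(rng.integers(2**31)),
            )
            bc = bray_curtis(matrix)
            ord_res = nmds(bc, seed=int(rng.integers(2**31)))
            an = anosim(
                bc, assign.assignments, config.n_permutations,
                seed=int(rng.integers(2**31)),
            )
            (out / "enterotypes.tsv").write_text(
                "sample_id\tgroup\ttrue_group\n"
                + "".join(
                    f"{s}\t{g}\t{truth_labels.get(s, '')}\n"
                    for s, g in sorted(assign.assignments.items())
                )
            )
            (out / "ordination.tsv").write_text(
                "sample_id\tx\ty\n"
                + "".join(
                    f"{s}\t{x:.10g}\t{y:.10g}\n"
                    for s, (x, y) in zip(ord_res.sample_ids, ord_res.coordinates)
                )
            )
            (out / "anosim.json").write_text(
                json.dumps(
                    {
                        "R": an.R, "p_value": an.p_value,
                        "n_permutations": an.n_permutations,
                        "group_sizes": an.group_sizes,
                        "nmds_stress": ord_res.stress,
                    },
                    indent=2, sort_keys=True,
                )
            )
            stages_run.append("enterotypes")

        stage = "summary"
        (out / "summary.tsv").write_text(
            "metric\tvalue\n"
            + f"contigs_total\t{len(contigs)}\n"
            + f"contigs_retained\t{len(retained)}\n"
            + f"contigs_passed\t{sum(h.passed for h in hits)}\n"
            + f"binned_phage\t{counts['phage']}\n"
            + f"binned_non_phage\t{counts['non_phage']}\n"
            + f"binned_unclassified\t{counts['unclassified']}\n"
        )
        provenance = {
            "version": __version__,
            "stages": stages_run,
            "config": asdict(config),
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True)
        )
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
    return out
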