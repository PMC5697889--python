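"""Synthetic two-host community generator with known ground truth.

Emulates the study design the pipeline targets: two host-labelled fecal
communities (host A sampled at 3 time-points, host B at 5), each a set of
population genomes with lognormal relative abundances.  Contig mean depth in
a sample is ``depth_mean x genome abundance x multiplicative lognormal
noise`` whose coefficient of variation is the single noise knob (the pipeline
consumes mean depths, not reads, so read-count noise models are out of
scope).  Genomes carry KOs drawn from shared plus host-differential pathway
pools with configurable carriage probabilities, and CAZy/auxiliary-activity
domains at host-specific rates.  Bins are corrupted to mimic real
metagenome-assembled genomes: completeness by removing whole contigs,
contamination by donating another genome's unbinned contigs.

Ground truth (true abundances, true differential pathways, true bin
membership, true proteome divergence) is returned alongside the data so every
downstream stage can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import io as mgio
from .catalog import default_catalog
from .model import (
    AnnotatedCDS,
    CoverageTable,
    FunctionCatalog,
    GenomeBin,
    SampleGroup,
    ValidationError,
    validate_bins,
    validate_cds_list,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# Robinson-Robinson style background frequencies, renormalised over 20 letters
AA_FREQS = np.array(
    [
        0.078, 0.019, 0.053, 0.063, 0.039, 0.072, 0.022, 0.053, 0.059, 0.091,
        0.022, 0.043, 0.052, 0.042, 0.051, 0.068, 0.059, 0.066, 0.014, 0.032,
    ]
)
AA_FREQS = AA_FREQS / AA_FREQS.sum()

# GH families outside the four lignocellulose roles, for background annotation
OTHER_GH_POOL = ("GH13", "GH20", "GH23", "GH25", "GH31", "GH36", "GH57", "GH77")
AA_FAMILY_POOL = ("AA1", "AA2", "AA3", "AA4", "AA6", "AA7")


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped defaults: tune deliberately, not per-test."""

    n_genomes: int = 12  # per host
    n_samples_a: int = 3
    n_samples_b: int = 5
    contigs_per_genome: tuple[int, int] = (6, 10)
    contig_length: tuple[int, int] = (20_000, 80_000)
    cds_per_contig: tuple[int, int] = (15, 25)
    depth_mean: float = 20.0
    coverage_noise_cv: float = 0.2
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    n_shared_pathways: int = 40
    n_differential_pathways: int = 5  # per host
    kos_per_pathway: int = 5
    carriage_prob: float = 0.2
    differential_effect: float = 4.0
    gh_prob: float = 0.10  # per-CDS chance of a GH domain
    aa_prob: tuple[float, float] = (0.03, 0.01)  # per-CDS AA chance, per host
    completeness_range: tuple[float, float] = (60.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 5.0)
    proteome_divergence: tuple[float, ...] = (0.05, 0.2)
    protein_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genomes", "n_samples_a", "n_samples_b", "kos_per_pathway"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("carriage_prob", "gh_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        for p in self.aa_prob:
            if not 0.0 <= p <= 1.0:
                raise ValidationError("aa_prob entries must lie in [0, 1]")
        for d in self.proteome_divergence:
            if not 0.0 <= d < 1.0:
                raise ValidationError("proteome divergence must lie in [0, 1)")
        if self.coverage_noise_cv < 0:
            raise ValidationError("coverage_noise_cv must be >= 0")
        if self.differential_effect < 0:
            raise ValidationError("differential_effect must be >= 0")
        max_kos = (
            self.n_shared_pathways + 2 * self.n_differential_pathways
        ) * self.kos_per_pathway
        min_cds = self.contigs_per_genome[0] * self.cds_per_contig[0]
        if max_kos > 0 and min_cds < 1:
            raise ValidationError("genomes must have at least one CDS")


@dataclass
class HostDataset:
    """Everything the pipeline reads for one host community."""

    host: str
    samples: list[str]
    cds: list[AnnotatedCDS]
    coverage: CoverageTable
    bins: list[GenomeBin]  # completeness/contamination-corrupted
    proteomes: dict[str, dict[str, str]]  # genome -> protein id -> sequence
    genome_contigs: dict[str, list[str]]

    @property
    def group(self) -> SampleGroup:
        return SampleGroup(group_id=self.host, sample_ids=tuple(self.samples))


@dataclass
class SyntheticTruth:
    """Generator ground truth for recovery assertions."""

    abundance: dict[str, dict[str, dict[str, float]]]  # host -> genome -> sample
    differential_pathways: dict[str, frozenset[str]]  # host -> pathways
    divergence_pairs: list[tuple[str, str, float]]  # (genome_a, genome_b, d)
    true_bins: dict[str, list[GenomeBin]]  # host -> uncorrupted bins
    genome_sizes: dict[str, dict[str, int]]  # host -> genome -> bp


@dataclass
class SyntheticCommunity:
    config: SimConfig
    catalog: FunctionCatalog
    hosts: dict[str, HostDataset]
    truth: SyntheticTruth


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV; cv=0 -> 1."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=AA_FREQS)
    return "".join(AMINO_ACIDS[i] for i in idx)


def mutate_proteome(
    proteome: dict[str, str], divergence: float, seed: int
) -> dict[str, str]:
    """Per-site substitution to a random different residue with probability d.

    Expected per-protein identity is (1 - d); lengths are preserved.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValidationError(f"divergence {divergence} outside [0, 1)")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for pid, seq in proteome.items():
        if divergence == 0.0:
            out[pid] = seq
            continue
        chars = list(seq)
        hits = np.nonzero(rng.random(len(chars)) < divergence)[0]
        for i in hits:
            choices = [a for a in AMINO_ACIDS if a != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
        out[pid] = "".join(chars)
    return out


def _build_catalog(config: SimConfig) -> tuple[FunctionCatalog, dict[str, frozenset[str]]]:
    """Shared + per-host differential pathway pools with disjoint KO sets."""
    ko_to_pathways: dict[str, frozenset[str]] = {}
    pathway_category: dict[str, str] = {}
    differential: dict[str, frozenset[str]] = {}
    ko_counter = 0

    def add_pathways(prefix: str, n: int) -> list[str]:
        nonlocal ko_counter
        names = []
        for i in range(n):
            pw = f"{prefix}{i + 1:03d}"
            pathway_category[pw] = f"1.{(len(pathway_category) % 11) + 1}"
            for _ in range(config.kos_per_pathway):
                ko_counter += 1
                ko_to_pathways[f"K{ko_counter:05d}"] = frozenset({pw})
            names.append(pw)
        return names

    add_pathways("shared_pw", config.n_shared_pathways)
    differential["hostA"] = frozenset(
        add_pathways("diffA_pw", config.n_differential_pathways)
    )
    differential["hostB"] = frozenset(
        add_pathways("diffB_pw", config.n_differential_pathways)
    )
    catalog = default_catalog(
        ko_to_pathways=ko_to_pathways, pathway_category=pathway_category
    )
    return catalog, differential


def _pathway_kos(catalog: FunctionCatalog, pathway: str) -> list[str]:
    return sorted(
        ko for ko, pws in catalog.ko_to_pathways.items() if pathway in pws
    )


def _corrupt_bins(
    true_bins: list[GenomeBin],
    lengths: dict[str, int],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[GenomeBin]:
    """Remove contigs to simulate incompleteness, donate to simulate contamination."""
    kept: dict[str, list[str]] = {}
    removed_pool: list[tuple[str, str]] = []  # (donor bin, contig)
    for b in true_bins:
        target = rng.uniform(*config.completeness_range) / 100.0
        contigs = sorted(b.contig_ids)
        rng.shuffle(contigs)
        total = sum(lengths[c] for c in contigs)
        keep: list[str] = []
        removed_bp = 0
        for c in contigs:
            if keep and (removed_bp + lengths[c]) / total <= 1.0 - target:
                removed_bp += lengths[c]
                removed_pool.append((b.bin_id, c))
            else:
                keep.append(c)
        kept[b.bin_id] = keep
    rng.shuffle(removed_pool)

    out: list[GenomeBin] = []
    pool_idx = 0
    for b in true_bins:
        own = list(kept[b.bin_id])
        own_bp = sum(lengths[c] for c in own)
        total_bp = sum(lengths[c] for c in sorted(b.contig_ids))
        target_contam = rng.uniform(*config.contamination_range) / 100.0
        donated: list[str] = []
        donated_bp = 0
        while pool_idx < len(removed_pool):
            donor, contig = removed_pool[pool_idx]
            if donor == b.bin_id:
                pool_idx += 1
                continue
            if donated_bp + lengths[contig] > target_contam * own_bp:
                break
            donated.append(contig)
            donated_bp += lengths[contig]
            pool_idx += 1
        completeness = 100.0 * own_bp / total_bp
        contamination = 100.0 * donated_bp / own_bp if own_bp else 0.0
        out.append(
            GenomeBin(
                bin_id=b.bin_id,
                contig_ids=frozenset(own + donated),
                completeness=completeness,
                contamination=min(contamination, 100.0),
                size_bp=own_bp + donated_bp,
                taxonomy=b.taxonomy,
            )
        )
    validate_bins(out)
    return out


def _simulate_host(
    host: str,
    n_samples: int,
    sample_prefix: str,
    aa_prob: float,
    differential_here: frozenset[str],
    differential_other: frozenset[str],
    catalog: FunctionCatalog,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[HostDataset, dict[str, dict[str, float]], list[GenomeBin], dict[str, int]]:
    samples = [f"{sample_prefix}_T{i + 1}" for i in range(n_samples)]
    genome_ids = [f"{host}_g{i + 1:02d}" for i in range(config.n_genomes)]

    # genome skeletons: contigs, lengths, CDS slots
    genome_contigs: dict[str, list[str]] = {}
    lengths: dict[str, int] = {}
    cds_by_genome: dict[str, list[AnnotatedCDS]] = {g: [] for g in genome_ids}
    for g in genome_ids:
        n_contigs = int(rng.integers(config.contigs_per_genome[0],
                                     config.contigs_per_genome[1] + 1))
        contigs = [f"{g}_c{j + 1:02d}" for j in range(n_contigs)]
        genome_contigs[g] = contigs
        for contig in contigs:
            lengths[contig] = int(rng.integers(config.contig_length[0],
                                               config.contig_length[1] + 1))
            n_cds = int(rng.integers(config.cds_per_contig[0],
                                     config.cds_per_contig[1] + 1))
            pos = 1
            for k in range(n_cds):
                span = 3 * config.protein_length
                cds_by_genome[g].append(
                    AnnotatedCDS(
                        cds_id=f"{contig}_orf{k + 1:03d}",
                        contig_id=contig,
                        start=pos,
                        end=pos + span - 1,
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
                pos += span + 50

    # KO content: shared pool at baseline carriage, own differential pool at
    # baseline x effect, the other host's differential pool at baseline
    p_base = config.carriage_prob
    p_diff = min(1.0, p_base * config.differential_effect)
    all_pathways = sorted(catalog.pathway_category)
    for g in genome_ids:
        carried: list[str] = []
        for pw in all_pathways:
            if pw in differential_here:
                p = p_diff
            elif pw in differential_other:
                p = p_base
            else:
                p = p_base
            for ko in _pathway_kos(catalog, pw):
                if rng.random() < p:
                    carried.append(ko)
        slots = cds_by_genome[g]
        if len(carried) > len(slots):
            raise ValidationError(
                f"infeasible config: genome {g} carries {len(carried)} KOs "
                f"but has only {len(slots)} CDSs"
            )
        chosen = rng.choice(len(slots), size=len(carried), replace=False)
        for ko, idx in zip(carried, chosen):
            slots[idx] = replace(slots[idx], ko=ko)

    # CAZy domains: lignocellulolytic + other GH background, host-rate AA
    ligno = sorted(catalog.gh_category)
    for g in genome_ids:
        slots = cds_by_genome[g]
        for i, cds in enumerate(slots):
            domains: list[str] = []
            if rng.random() < config.gh_prob:
                pool = ligno + list(OTHER_GH_POOL)
                domains.append(pool[rng.integers(len(pool))])
            if rng.random() < aa_prob:
                domains.append(AA_FAMILY_POOL[rng.integers(len(AA_FAMILY_POOL))])
            if domains:
                slots[i] = replace(cds, cazy_domains=tuple(domains))

    # abundances and coverage
    base = rng.lognormal(config.abundance_mu, config.abundance_sigma,
                         size=len(genome_ids))
    base = base / base.sum()
    genome_bp = {g: sum(lengths[c] for c in genome_contigs[g]) for g in genome_ids}
    weighted = np.array([base[i] * genome_bp[g] for i, g in enumerate(genome_ids)])
    read_fraction = weighted / weighted.sum()

    depth: dict[str, dict[str, float]] = {}
    for i, g in enumerate(genome_ids):
        for contig in genome_contigs[g]:
            noise = _lognormal_noise(rng, config.coverage_noise_cv, len(samples))
            depth[contig] = {
                s: config.depth_mean * float(base[i]) * float(noise[j])
                for j, s in enumerate(samples)
            }
    coverage = CoverageTable(samples=samples, depth=depth, contig_lengths=lengths)

    truth_abundance = {
        g: {s: float(read_fraction[i]) for s in samples}
        for i, g in enumerate(genome_ids)
    }

    true_bins = [
        GenomeBin(
            bin_id=g,
            contig_ids=frozenset(genome_contigs[g]),
            completeness=100.0,
            contamination=0.0,
            size_bp=genome_bp[g],
            taxonomy=f"synthetic;{host};{g}",
        )
        for g in genome_ids
    ]
    bins = _corrupt_bins(true_bins, lengths, config, rng)

    # proteomes: i.i.d. background-frequency residues per CDS
    proteomes: dict[str, dict[str, str]] = {}
    for g in genome_ids:
        proteomes[g] = {
            cds.cds_id: random_protein(rng, config.protein_length)
            for cds in cds_by_genome[g]
        }

    cds_list = [c for g in genome_ids for c in cds_by_genome[g]]
    validate_cds_list(cds_list)
    dataset = HostDataset(
        host=host,
        samples=samples,
        cds=cds_list,
        coverage=coverage,
        bins=bins,
        proteomes=proteomes,
        genome_contigs=genome_contigs,
    )
    return dataset, truth_abundance, true_bins, genome_bp


def simulate_community(config: SimConfig) -> SyntheticCommunity:
    """Generate both host communities plus ground truth, reproducibly from seed."""
    rng = np.random.default_rng(config.seed)
    catalog, differential = _build_catalog(config)

    ds_a, ab_a, tb_a, bp_a = _simulate_host(
        "hostA", config.n_samples_a, "A", config.aa_prob[0],
        differential["hostA"], differential["hostB"], catalog, config, rng,
    )
    ds_b, ab_b, tb_b, bp_b = _simulate_host(
        "hostB", config.n_samples_b, "B", config.aa_prob[1],
        differential["hostB"], differential["hostA"], catalog, config, rng,
    )

    # controlled-divergence proteome pairs: host B counterpart genomes get a
    # mutated copy of the host A proteome at the configured divergence
    pairs: list[tuple[str, str, float]] = []
    for i, d in enumerate(config.proteome_divergence):
        if i >= config.n_genomes:
            break
        ga = f"hostA_g{i + 1:02d}"
        gb = f"hostB_g{i + 1:02d}"
        source = ds_a.proteomes[ga]
        target_ids = list(ds_b.proteomes[gb])
        mutated = mutate_proteome(
            source, d, seed=int(rng.integers(2**31 - 1))
        )
        renamed = dict(zip(target_ids, mutated.values()))
        # pad/trim to the target genome's own protein count
        ds_b.proteomes[gb] = {
            pid: renamed.get(pid, seq) for pid, seq in ds_b.proteomes[gb].items()
        }
        pairs.append((ga, gb, d))

    if config.n_differential_pathways == 0:
        differential = {"hostA": frozenset(), "hostB": frozenset()}

    truth = SyntheticTruth(
        abundance={"hostA": ab_a, "hostB": ab_b},
        differential_pathways=differential,
        divergence_pairs=pairs,
        true_bins={"hostA": tb_a, "hostB": tb_b},
        genome_sizes={"hostA": bp_a, "hostB": bp_b},
    )
    return SyntheticCommunity(
        config=config,
        catalog=catalog,
        hosts={"hostA": ds_a, "hostB": ds_b},
        truth=truth,
    )


def spike_differential(
    dataset: HostDataset,
    catalog: FunctionCatalog,
    pathway: str,
    effect: float,
    carriage_prob: float = 0.2,
    seed: int = 0,
) -> HostDataset:
    """Raise a pathway's KO carriage in one host's genomes by a fold effect.

    Baseline carriage ``carriage_prob`` is lifted to ``min(1, prob x effect)``
    (an infinite effect forces full carriage even on an empty background);
    genomes already carrying a KO are untouched, so ``effect <= 1`` returns
    the dataset unchanged.
    """
    if pathway not in catalog.pathway_category and not any(
        pathway in pws for pws in catalog.ko_to_pathways.values()
    ):
        raise ValidationError(f"unknown pathway: {pathway}")
    if effect <= 1.0:
        return dataset
    if np.isinf(effect):
        p_new = 1.0
    else:
        p_new = min(1.0, carriage_prob * effect)
    p_add = (
        (p_new - carriage_prob) / (1.0 - carriage_prob)
        if carriage_prob < 1.0
        else 0.0
    )
    rng = np.random.default_rng(seed)
    kos = _pathway_kos(catalog, pathway)
    cds_by_id = {c.cds_id: i for i, c in enumerate(dataset.cds)}
    new_cds = list(dataset.cds)
    contig_owner = {
        contig: g for g, contigs in dataset.genome_contigs.items() for contig in contigs
    }
    for g in sorted(dataset.genome_contigs):
        genome_cds = [
            c for c in new_cds if contig_owner.get(c.contig_id) == g
        ]
        carried = {c.ko for c in genome_cds if c.ko}
        free = [c for c in genome_cds if c.ko is None]
        rng.shuffle(free)
        for ko in kos:
            if ko in carried or not free:
                continue
            if rng.random() < p_add:
                slot = free.pop()
                new_cds[cds_by_id[slot.cds_id]] = replace(slot, ko=ko)
    return HostDataset(
        host=dataset.host,
        samples=list(dataset.samples),
        cds=new_cds,
        coverage=dataset.coverage,
        bins=dataset.bins,
        proteomes=dataset.proteomes,
        genome_contigs=dataset.genome_contigs,
    )


def write_community(community: SyntheticCommunity, outdir: str) -> None:
    """Write the exact TSV/FASTA formats of the readers plus truth.yaml."""
    import os

    from .catalog import write_ko_pathway_table

    os.makedirs(outdir, exist_ok=True)
    write_ko_pathway_table(
        community.catalog, os.path.join(outdir, "ko_pathways.tsv")
    )
    for host, ds in community.hosts.items():
        prefix = os.path.join(outdir, host)
        mgio.write_cds_table(ds.cds, prefix + "_cds.tsv")
        mgio.write_coverage_table(ds.coverage, prefix + "_coverage.tsv")
        mgio.write_bins(ds.bins, prefix + "_bin_membership.tsv",
                        prefix + "_bin_metadata.tsv")
        for g, proteome in ds.proteomes.items():
            mgio.write_proteome(proteome, os.path.join(outdir, f"{g}.faa"))
    truth = community.truth
    payload = {
        "abundance": truth.abundance,
        "differential_pathways": {
            h: sorted(pws) for h, pws in truth.differential_pathways.items()
        },
        "divergence_pairs": [list(p) for p in truth.divergence_pairs],
        "genome_sizes": truth.genome_sizes,
    }
    with open(os.path.join(outdir, "truth.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
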