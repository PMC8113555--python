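"""Ground-truth-bearing synthetic data for every pipeline stage.

Four generators emulate the statistical structure of the real inputs
so that every analysis can be exercised end-to-end with a known
answer:

* ``simulate_pulldown`` — label-free pulldown intensity tables:
  log-normal protein abundances, a minority of bait-enriched spiked
  proteins, replicate noise, and intensity-dependent (missing-not-at-
  random) dropout that is logistic in the latent log2 abundance —
  exactly the left-censoring the low-tail imputation presupposes.
* ``simulate_dml`` — forward/reverse dimethyl-label ratio columns with
  the label-switch orientation convention (stored as medium/light).
* ``simulate_fish_stacks`` — 3D stacks of Gaussian telomeric foci on a
  noisy background, with per-strain amplitude scale factors playing
  the role of ground-truth relative telomere length.
* ``simulate_genomes`` — toy genome pairs with one-to-one orthologs,
  BLAST-like hit tables, and single-gene relocations that break local
  synteny by construction.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ProteinGroupTable, SampleInfo
from .qfish import ImageStack3D

__all__ = [
    "PulldownSimParams",
    "FishSimParams",
    "GenomeSimParams",
    "simulate_pulldown",
    "simulate_dml",
    "simulate_fish_stacks",
    "simulate_genomes",
]


@dataclass(frozen=True)
class PulldownSimParams:
    """Conditions for the pulldown/IP intensity simulator.

    Defaults mirror a moderately deep affinity-enrichment experiment:
    2000 protein groups, 10 true binders at 16-fold enrichment, 4
    replicates per condition, log2 abundances ~ N(25, 2), replicate
    noise 0.5 log2 units, and logistic MNAR dropout centered at log2
    intensity 22 with slope 1.5 (so low-abundance proteins drop out).
    """

    n_proteins: int = 2000
    n_spiked: int = 10
    log2_effect: float = 4.0
    n_reps: int = 4
    base_mean_log2: float = 25.0
    base_sd_log2: float = 2.0
    noise_sd_log2: float = 0.5
    dropout_midpoint: float = 22.0
    dropout_slope: float = 1.5
    contaminant_fraction: float = 0.02
    reverse_fraction: float = 0.02
    dml_missing_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spiked > self.n_proteins:
            raise ValueError("n_spiked cannot exceed n_proteins")
        if self.dropout_slope <= 0:
            raise ValueError("dropout_slope must be positive (dropout decreasing in intensity)")


def _dropout_prob(latent_log2: np.ndarray, p: PulldownSimParams) -> np.ndarray:
    """P(missing) decreasing logistically in the latent log2 intensity,
    with ``dropout_slope`` the logistic steepness coefficient."""
    return 1.0 / (1.0 + np.exp(p.dropout_slope * (latent_log2 - p.dropout_midpoint)))


def _flag_rows(rng: np.random.Generator, p: PulldownSimParams, columns: list[str]):
    """Extra contaminant/reverse decoy rows appended to the matrix."""
    rows = []
    n_cont = int(round(p.contaminant_fraction * p.n_proteins))
    n_rev = int(round(p.reverse_fraction * p.n_proteins))
    for prefix, flag, n in (("CONT", "contaminant", n_cont), ("REV", "reverse", n_rev)):
        for i in range(n):
            inten = 2.0 ** rng.normal(p.base_mean_log2, p.base_sd_log2, size=len(columns))
            rows.append((f"{prefix}_{i:04d}", flag, inten))
    return rows


def simulate_pulldown(
    p: PulldownSimParams = PulldownSimParams(),
) -> tuple[ProteinGroupTable, pd.DataFrame]:
    """Simulate an LFQ bait-vs-control pulldown with spiked binders.

    Returns the table (linear-scale intensities, NaN = dropped out,
    flagged decoy rows appended) and a truth frame with the spiked
    protein ids.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]
    spiked_idx = rng.choice(n, size=p.n_spiked, replace=False) if p.n_spiked else np.array([], dtype=int)
    spiked = np.zeros(n, dtype=bool)
    spiked[spiked_idx] = True

    latent = rng.normal(p.base_mean_log2, p.base_sd_log2, size=n)
    bait_latent = latent + np.where(spiked, p.log2_effect, 0.0)

    cols: dict[str, np.ndarray] = {}
    sheet: list[SampleInfo] = []
    for cond, cond_latent in (("bait", bait_latent), ("control", latent)):
        for r in range(1, p.n_reps + 1):
            name = f"{cond}_{r}"
            obs = cond_latent + rng.normal(0.0, p.noise_sd_log2, size=n)
            drop = rng.random(n) < _dropout_prob(cond_latent, p)
            vals = 2.0**obs
            vals[drop] = np.nan
            cols[name] = vals
            sheet.append(SampleInfo(name=name, condition=cond, replicate=r))

    mat = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))
    flags = pd.DataFrame(
        {"contaminant": False, "reverse": False, "only_by_site": False}, index=mat.index
    )
    extra = _flag_rows(rng, p, list(mat.columns))
    if extra:
        extra_mat = pd.DataFrame(
            [dict(zip(mat.columns, inten)) for _, _, inten in extra],
            index=pd.Index([fid for fid, _, _ in extra], name="protein_id"),
        )
        extra_flags = pd.DataFrame(
            {
                "contaminant": [flag == "contaminant" for _, flag, _ in extra],
                "reverse": [flag == "reverse" for _, flag, _ in extra],
                "only_by_site": [flag == "only_by_site" for _, flag, _ in extra],
            },
            index=extra_mat.index,
        )
        mat = pd.concat([mat, extra_mat])
        flags = pd.concat([flags, extra_flags])

    truth = pd.DataFrame({"protein_id": ids, "spiked": spiked})
    table = ProteinGroupTable(intensities=mat, flags=flags.astype(bool), sample_sheet=sheet)
    return table, truth


def simulate_dml(
    p: PulldownSimParams = PulldownSimParams(),
) -> tuple[ProteinGroupTable, pd.DataFrame]:
    """Simulate forward/reverse dimethyl-label ratio columns.

    Spiked proteins carry a true bait/control ratio of 2**log2_effect
    in both sets; null proteins have ratio 2**N(0, noise). Stored
    ratios follow the medium/light convention with the label switch:
    the forward set carried bait in the light channel (so its stored
    ratio is control/bait) and the reverse set in the medium channel.
    Per-set missingness is independent.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]
    spiked_idx = rng.choice(n, size=p.n_spiked, replace=False) if p.n_spiked else np.array([], dtype=int)
    spiked = np.zeros(n, dtype=bool)
    spiked[spiked_idx] = True
    true_log2 = np.where(spiked, p.log2_effect, 0.0)

    fwd_bc = 2.0 ** (true_log2 + rng.normal(0.0, p.noise_sd_log2, size=n))
    rev_bc = 2.0 ** (true_log2 + rng.normal(0.0, p.noise_sd_log2, size=n))
    fwd_stored = 1.0 / fwd_bc  # bait was light: stored M/L = control/bait
    rev_stored = rev_bc  # bait was medium: stored M/L = bait/control
    fwd_stored[rng.random(n) < p.dml_missing_rate] = np.nan
    rev_stored[rng.random(n) < p.dml_missing_rate] = np.nan

    mat = pd.DataFrame(
        {"ratio_fwd": fwd_stored, "ratio_rev": rev_stored},
        index=pd.Index(ids, name="protein_id"),
    )
    flags = pd.DataFrame(
        {"contaminant": False, "reverse": False, "only_by_site": False}, index=mat.index
    )
    sheet = [
        SampleInfo("ratio_fwd", "bait", 1, "dml", dml_channel="light", dml_set="forward"),
        SampleInfo("ratio_rev", "bait", 1, "dml", dml_channel="medium", dml_set="reverse"),
    ]
    truth = pd.DataFrame({"protein_id": ids, "spiked": spiked})
    return ProteinGroupTable(intensities=mat, flags=flags, sample_sheet=sheet), truth


@dataclass(frozen=True)
class FishSimParams:
    """Conditions for the 3D telomere-FISH stack simulator.

    Foci are isotropic-in-plane 3D Gaussians well above a low, noisy
    background, as for a bright PNA telomeric probe; the per-strain
    amplitude scale factor is the ground-truth relative telomere
    length. ``n_images`` stacks are generated per strain.
    """

    shape: tuple[int, int, int] = (16, 64, 64)
    n_foci: int = 8
    amplitude: float = 400.0
    amplitude_cv_log2: float = 0.25
    sigma_voxels: tuple[float, float, float] = (1.2, 2.0, 2.0)
    background: float = 5.0
    noise_sd: float = 2.0
    n_images: int = 10
    margin_sigmas: float = 3.0
    seed: int = 0


def _gaussian_blob(shape, center, sigma, amplitude) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        ((zz - center[0]) / sigma[0]) ** 2
        + ((yy - center[1]) / sigma[1]) ** 2
        + ((xx - center[2]) / sigma[2]) ** 2
    )
    return amplitude * np.exp(-0.5 * d2)


def simulate_fish_stacks(
    p: FishSimParams, strains: dict[str, float]
) -> tuple[list[ImageStack3D], pd.DataFrame]:
    """Simulate qFISH stacks for strains with known scale factors.

    Returns the stacks and a truth frame with one row per focus
    (strain, image, ground-truth integrated density pre-noise).
    """
    rng = np.random.default_rng(p.seed)
    stacks: list[ImageStack3D] = []
    truth_rows = []
    margins = [max(1, int(np.ceil(p.margin_sigmas * s))) for s in p.sigma_voxels]
    for strain, scale in strains.items():
        if scale <= 0:
            raise ValueError(f"scale factor for {strain!r} must be positive")
        for img in range(p.n_images):
            image_id = f"{strain}_img{img:02d}"
            field_img = np.full(p.shape, p.background, dtype=float)
            for f in range(p.n_foci):
                center = [
                    rng.uniform(m, dim - 1 - m) for m, dim in zip(margins, p.shape)
                ]
                amp = scale * p.amplitude * 2.0 ** rng.normal(0.0, p.amplitude_cv_log2)
                blob = _gaussian_blob(p.shape, center, p.sigma_voxels, amp)
                field_img += blob
                truth_rows.append(
                    {
                        "strain": strain,
                        "image_id": image_id,
                        "focus": f,
                        "amplitude": amp,
                        "true_integrated_density": float(blob.sum()),
                    }
                )
            noisy = field_img + rng.normal(0.0, p.noise_sd, size=p.shape)
            np.clip(noisy, 0.0, None, out=noisy)
            stacks.append(
                ImageStack3D(voxels=noisy, strain=strain, image_id=image_id)
            )
    return stacks, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class GenomeSimParams:
    """Conditions for the toy genome-pair simulator.

    Two species share ``ortholog_fraction`` of their genes one-to-one
    with conserved gene order; ``n_relocations`` ortholog genes of
    species B are each moved alone to a fresh scaffold, breaking local
    synteny for the corresponding focal pair by construction. True
    ortholog pairs receive mutual best hits with E-values below 1e-20;
    decoy hits sit above 1e-10.
    """

    n_scaffolds: int = 3
    n_genes_per_scaffold: int = 40
    ortholog_fraction: float = 0.9
    n_relocations: int = 3
    decoy_hit_prob: float = 0.3
    gene_length: int = 500
    gene_spacing: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ortholog_fraction <= 1):
            raise ValueError("ortholog_fraction must be in (0, 1]")
        if self.n_relocations > self.n_scaffolds * self.n_genes_per_scaffold:
            raise ValueError("more relocations than genes")


def simulate_genomes(p: GenomeSimParams = GenomeSimParams()):
    """Simulate an annotated genome pair with hit tables and truth.

    Returns ``(ann_a, ann_b, hits_ab, hits_ba, truth)`` where the
    annotations are :class:`~telopull.orthology.GeneAnnotation`, hit
    tables are BLAST outfmt-6 frames, and ``truth`` gives, per species-
    A gene: its ortholog (if any), whether its ortholog was relocated,
    and the expected local-synteny verdict under both window modes for
    k = 13, derived purely from the construction (positional neighbor
    counting), independent of the synteny caller.
    """
    from .orthology import BLAST6_COLUMNS, GeneAnnotation

    rng = np.random.default_rng(p.seed)
    k = 13

    genes_a, genes_b = [], []
    a_order: list[list[str]] = []  # per scaffold, A gene ids in order
    ortholog_of: dict[str, str] = {}
    has_ortholog: dict[str, bool] = {}
    for s in range(p.n_scaffolds):
        scaffold_genes = []
        for i in range(p.n_genes_per_scaffold):
            ga = f"A_s{s}_g{i:03d}"
            start = 1 + i * p.gene_spacing
            genes_a.append(
                {"id": ga, "scaffold": f"A_scaf{s}", "start": start, "end": start + p.gene_length}
            )
            scaffold_genes.append(ga)
            ortho = rng.random() < p.ortholog_fraction
            has_ortholog[ga] = ortho
            if ortho:
                gb = f"B_s{s}_g{i:03d}"
                ortholog_of[ga] = gb
                genes_b.append(
                    {"id": gb, "scaffold": f"B_scaf{s}", "start": start, "end": start + p.gene_length}
                )
        a_order.append(scaffold_genes)

    # relocate n_relocations B orthologs, each alone to a fresh scaffold
    ortho_a_genes = [g for g in ortholog_of]
    reloc_a = set(
        rng.choice(ortho_a_genes, size=min(p.n_relocations, len(ortho_a_genes)), replace=False)
    )
    reloc_b = {ortholog_of[g] for g in reloc_a}
    for j, row in enumerate(genes_b):
        if row["id"] in reloc_b:
            row["scaffold"] = f"B_reloc{row['id']}"
            row["start"], row["end"] = 1, 1 + p.gene_length

    ann_a = GeneAnnotation(pd.DataFrame(genes_a))
    ann_b = GeneAnnotation(pd.DataFrame(genes_b))

    # hit tables: mutual best hits for true pairs, decoys elsewhere
    rows_ab, rows_ba = [], []

    def _hit(q, s, evalue, bitscore):
        return dict(
            qseqid=q, sseqid=s, pident=80.0, length=300, mismatch=60, gapopen=2,
            qstart=1, qend=300, sstart=1, send=300, evalue=evalue, bitscore=bitscore,
        )

    all_b = [r["id"] for r in genes_b]
    for ga in (r["id"] for r in genes_a):
        if has_ortholog[ga]:
            gb = ortholog_of[ga]
            e1 = 10.0 ** (-rng.uniform(20.5, 50.0))
            e2 = 10.0 ** (-rng.uniform(20.5, 50.0))
            bs = rng.uniform(300.0, 600.0)
            rows_ab.append(_hit(ga, gb, e1, bs))
            rows_ba.append(_hit(gb, ga, e2, bs))
        if rng.random() < p.decoy_hit_prob and all_b:
            decoy = str(rng.choice(all_b))
            if decoy != ortholog_of.get(ga):
                e = 10.0 ** (-rng.uniform(1.0, 9.0))
                rows_ab.append(_hit(ga, decoy, e, rng.uniform(30.0, 60.0)))

    hits_ab = pd.DataFrame(rows_ab, columns=BLAST6_COLUMNS)
    hits_ba = pd.DataFrame(rows_ba, columns=BLAST6_COLUMNS)

    # ground truth by positional counting over the construction
    truth_rows = []
    for s, scaffold_genes in enumerate(a_order):
        for pos, ga in enumerate(scaffold_genes):
            if not has_ortholog[ga]:
                truth_rows.append(
                    {"gene_a": ga, "gene_b": "", "relocated": False,
                     "syntenic_any_side": None, "syntenic_both_sides": None}
                )
                continue
            relocated = ga in reloc_a

            def _support(neighbors: list[str]) -> bool:
                return any(
                    has_ortholog[nb] and nb not in reloc_a for nb in neighbors
                )

            up = scaffold_genes[max(0, pos - k): pos]
            down = scaffold_genes[pos + 1: pos + 1 + k]
            if relocated:
                any_side = both = False
            else:
                u, d = _support(up), _support(down)
                any_side, both = (u or d), (u and d)
            truth_rows.append(
                {"gene_a": ga, "gene_b": ortholog_of[ga], "relocated": relocated,
                 "syntenic_any_side": any_side, "syntenic_both_sides": both}
            )
    truth = pd.DataFrame(truth_rows)
    return ann_a, ann_b, hits_ab, hits_ba, truth
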