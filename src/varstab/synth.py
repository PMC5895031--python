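"""Seeded generators producing pipeline inputs with known ground truth.

Every generator takes an integer seed, draws from an isolated
``numpy.random.default_rng`` stream, and returns the generated data
together with a machine-readable truth manifest recording exactly the
parameters a recovery test needs.  Identical arguments and seed give
identical output.

Noise models are the simplest ones matching each assay's error structure:
categorical draws for predictor panels, per-coordinate isotropic Gaussian
fluctuations plus rigid-body motion for trajectories, and multiplicative
lognormal noise for densitometry.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .catalog import GeneAnnotation
from .chase import ChaseTimepoint
from .codons import AdaptivenessTable, load_usage_table, relative_adaptiveness
from .consensus import TOOLS
from .errors import GeneratorSpecError
from .traj import StructureFrame, Trajectory

_BASES = "ACGT"

#: Published-style vocabularies used to realise a damaging / benign call.
_DAMAGING_VOCAB = {
    "PROVEAN": ["Deleterious"],
    "SIFT": ["Damaging"],
    "PolyPhen2": ["probably damaging"],
    "PhD-SNP": ["Disease"],
    "SNAP2": ["Effect"],
    "SNPsGO": ["Disease"],
    "FATHMM": ["Damaging"],
    "IMutant3": ["Large decrease of stability", "Large decrease in stability"],
}
_BENIGN_VOCAB = {
    "PROVEAN": ["Neutral"],
    "SIFT": ["Tolerated"],
    "PolyPhen2": ["benign", "possibly damaging"],
    "PhD-SNP": ["Neutral"],
    "SNAP2": ["Neutral"],
    "SNPsGO": ["Neutral"],
    "FATHMM": ["Tolerated"],
    "IMutant3": ["Neutral"],
}


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# gene / variant catalog


def synthetic_gene(protein_length: int = 169, seed: int = 0) -> tuple[GeneAnnotation, str]:
    """A single-gene annotation (UTRs, 4 CDS exons, 3 introns) plus its CDS."""
    rng = np.random.default_rng(seed)
    cds_len = 3 * (protein_length + 1)
    exon_lens = [cds_len // 4] * 3 + [cds_len - 3 * (cds_len // 4)]
    pos = 1
    utr5 = ((pos, pos + 99),)
    pos += 100
    cds, introns = [], []
    for i, length in enumerate(exon_lens):
        cds.append((pos, pos + length - 1))
        pos += length
        if i < len(exon_lens) - 1:
            introns.append((pos, pos + 299))
            pos += 300
    utr3 = ((pos, pos + 199),)
    annotation = GeneAnnotation(
        transcript_id="SYN-1",
        protein_length=protein_length,
        cds_intervals=tuple(cds),
        utr5_intervals=utr5,
        utr3_intervals=utr3,
        intron_intervals=tuple(introns),
    )
    sense = sorted(
        c
        for c in ("".join(b) for b in itertools.product(_BASES, repeat=3))
        if str(Seq(c).translate()) != "*"
    )
    body = "".join(rng.choice(sense, size=protein_length - 1))
    sequence = "ATG" + body + "TAA"
    return annotation, sequence


def _genomic_position(annotation: GeneAnnotation, cds_offset: int) -> int:
    remaining = cds_offset
    for start, end in annotation.cds_intervals:
        length = end - start + 1
        if remaining < length:
            return start + remaining
        remaining -= length
    raise GeneratorSpecError(f"CDS offset {cds_offset} beyond CDS")


def _coding_change(
    rng: np.random.Generator, cds: str, synonymous: bool, codon_index: int | None = None
) -> tuple[int, str, str, str, int, str]:
    """(cds_offset, ref_base, alt_base, ref_aa, residue, alt_aa) for a
    single-base coding change of the requested synonymy."""
    n_codons = len(cds) // 3 - 1  # exclude the stop codon
    for _ in range(1000):
        ci = int(rng.integers(0, n_codons)) if codon_index is None else codon_index
        codon = cds[3 * ci : 3 * ci + 3]
        ref_aa = str(Seq(codon).translate())
        if ref_aa == "*":
            if codon_index is not None:
                break
            continue
        options = []
        for within in range(3):
            for alt in _BASES:
                if alt == codon[within]:
                    continue
                alt_codon = codon[:within] + alt + codon[within + 1 :]
                alt_aa = str(Seq(alt_codon).translate())
                if alt_aa == "*":
                    continue
                if (alt_aa == ref_aa) == synonymous:
                    options.append((within, alt, alt_aa))
        if options:
            within, alt, alt_aa = options[int(rng.integers(0, len(options)))]
            return 3 * ci + within, codon[within], alt, ref_aa, ci + 1, alt_aa
        if codon_index is not None:
            break
    raise GeneratorSpecError("could not realise the requested coding change")


@dataclass
class CatalogSim:
    """A synthetic variant catalog with its gene model and truth manifest."""

    table: pd.DataFrame
    annotation: GeneAnnotation
    cds: str
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        (outdir / "cds.fasta").write_text(f">{self.annotation.transcript_id}\n{self.cds}\n")
        _write_manifest(outdir, self.manifest)


def gen_variant_catalog(
    n: int,
    fractions: dict[str, float] | None = None,
    seed: int = 0,
    protein_length: int = 169,
    duplicate_positions: int = 0,
) -> CatalogSim:
    """Draw a class-labelled catalog over a synthetic gene.

    ``fractions`` gives the target composition over the four region
    classes (defaults mirror a gene body dominated by intronic variants).
    ``duplicate_positions`` plants that many residues carrying two distinct
    substitutions each; every other substituted residue is unique.
    """
    fractions = fractions or {
        "intronic": 0.824,
        "utr": 0.064,
        "coding_nonsynonymous": 0.064,
        "coding_synonymous": 0.048,
    }
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise GeneratorSpecError(f"fractions sum to {sum(fractions.values())}, not 1")
    if any(f < 0 for f in fractions.values()):
        raise GeneratorSpecError("negative class fraction")
    rng = np.random.default_rng(seed)
    annotation, cds = synthetic_gene(protein_length, seed=seed)
    classes = list(fractions)
    draws = rng.choice(len(classes), size=n, p=[fractions[c] for c in classes])
    rows, truth_rows = [], []
    ns_rows: list[int] = []
    for i, ci in enumerate(draws):
        cls = classes[int(ci)]
        row = {
            "id": f"syn{i:05d}",
            "position": None,
            "protein_change": None,
            "maf": None,
            "ref_base": None,
            "alt_base": None,
        }
        if cls == "intronic":
            start, end = annotation.intron_intervals[
                int(rng.integers(0, len(annotation.intron_intervals)))
            ]
            row["position"] = int(rng.integers(start, end + 1))
        elif cls == "utr":
            intervals = annotation.utr5_intervals + annotation.utr3_intervals
            start, end = intervals[int(rng.integers(0, len(intervals)))]
            row["position"] = int(rng.integers(start, end + 1))
        else:
            synonymous = cls == "coding_synonymous"
            offset, ref, alt, ref_aa, residue, alt_aa = _coding_change(rng, cds, synonymous)
            row["position"] = _genomic_position(annotation, offset)
            row["ref_base"], row["alt_base"] = ref, alt
            if not synonymous:
                row["protein_change"] = f"{ref_aa}{residue}{alt_aa}"
                ns_rows.append(i)
        if rng.random() < 0.9:
            row["maf"] = float(round(min(0.5, rng.lognormal(math.log(1e-4), 1.5)), 6))
        rows.append(row)
        truth_rows.append({"id": row["id"], "region_class": cls, "maf": row["maf"]})
    planted = _plant_duplicates(rng, rows, ns_rows, annotation, cds, duplicate_positions)
    table = pd.DataFrame(rows)
    manifest = {
        "n": n,
        "seed": seed,
        "fractions": fractions,
        "protein_length": protein_length,
        "duplicate_positions": planted,
        "truth": truth_rows,
    }
    return CatalogSim(table=table, annotation=annotation, cds=cds, manifest=manifest)


def _plant_duplicates(
    rng: np.random.Generator,
    rows: list[dict],
    ns_rows: list[int],
    annotation: GeneAnnotation,
    cds: str,
    k: int,
) -> list[int]:
    """Rewrite nsSNP tokens so exactly k residues carry two variants."""
    if k == 0 and not ns_rows:
        return []
    if 2 * k > len(ns_rows):
        raise GeneratorSpecError(
            f"{k} duplicate positions need {2 * k} nsSNP rows, have {len(ns_rows)}"
        )
    n_codons = len(cds) // 3 - 1
    if len(ns_rows) - k > n_codons:
        raise GeneratorSpecError("more nsSNP rows than available residues")
    chosen = rng.choice(n_codons, size=len(ns_rows) - k, replace=False) + 1
    # first k residues get a pair, the rest are unique
    targets = list(chosen[:k]) * 2 + list(chosen[k:])
    planted = sorted(int(r) for r in chosen[:k])
    for row_i, residue in zip(ns_rows, targets):
        row = rows[row_i]
        codon = cds[3 * (residue - 1) : 3 * (residue - 1) + 2 + 1]
        ref_aa = str(Seq(codon).translate())
        seen_alts = {
            rows[j]["protein_change"][-1]
            for j in ns_rows
            if rows[j] is not row
            and rows[j]["protein_change"]
            and rows[j]["protein_change"][1:-1] == str(residue)
        }
        for _ in range(100):
            offset, ref, alt, _, _, alt_aa = _coding_change(
                rng, cds, synonymous=False, codon_index=residue - 1
            )
            if alt_aa not in seen_alts:
                break
        else:  # pragma: no cover - exhausted alternatives
            raise GeneratorSpecError(f"no distinct substitution at residue {residue}")
        row["position"] = _genomic_position(annotation, offset)
        row["ref_base"], row["alt_base"] = ref, alt
        row["protein_change"] = f"{ref_aa}{residue}{alt_aa}"
    return planted


# ---------------------------------------------------------------------------
# predictor panels


@dataclass
class PanelSim:
    """Synthetic eight-tool predictor panels with planted vote counts."""

    table: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "panels.tsv", sep="\t", index=False)
        _write_manifest(outdir, self.manifest)


def gen_predictor_panels(
    n_rows: int = 52,
    votes: Sequence[int] | None = None,
    seed: int = 0,
) -> PanelSim:
    """Panels whose damaging-vote count per row equals the planted count.

    ``votes`` fixes the count per row (0..8); when omitted, counts are
    drawn uniformly over 0..8.  Truth labels follow the >= 5 rule.
    """
    rng = np.random.default_rng(seed)
    if votes is None:
        votes = rng.integers(0, 9, size=n_rows).tolist()
    votes = [int(v) for v in votes]
    if len(votes) != n_rows:
        raise GeneratorSpecError(f"{len(votes)} planted votes for {n_rows} rows")
    if any(not 0 <= v <= 8 for v in votes):
        raise GeneratorSpecError("planted votes must lie in 0..8")
    aa = "ACDEFGHIKLMNPQRSTVWY"
    rows, truth = [], []
    for i, v in enumerate(votes):
        damaging_tools = set(rng.choice(len(TOOLS), size=v, replace=False).tolist())
        row: dict = {"id": f"pan{i:04d}"}
        ref, alt = rng.choice(list(aa), size=2, replace=False)
        row["mutation"] = f"{ref}{int(rng.integers(2, 169))}{alt}"
        for t_i, tool in enumerate(TOOLS):
            vocab = _DAMAGING_VOCAB[tool] if t_i in damaging_tools else _BENIGN_VOCAB[tool]
            row[tool] = vocab[int(rng.integers(0, len(vocab)))]
        rows.append(row)
        truth.append({"id": row["id"], "votes": v, "label": "D" if v >= 5 else "N"})
    manifest = {"n_rows": n_rows, "seed": seed, "truth": truth}
    return PanelSim(table=pd.DataFrame(rows), manifest=manifest)


# ---------------------------------------------------------------------------
# coding sequences with planted rare-codon blocks


@dataclass
class CdsSim:
    """A CDS that is family-maximal outside planted low-adaptiveness blocks."""

    sequence: str
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "cds.fasta").write_text(">synthetic_cds\n" + self.sequence + "\n")
        _write_manifest(outdir, self.manifest)


def gen_cds(
    n_codons: int = 170,
    blocks: Sequence[tuple[int, int]] = ((100, 121),),
    seed: int = 0,
    adapt: AdaptivenessTable | None = None,
    include_stop: bool = True,
) -> CdsSim:
    """A CDS whose codons are family-maximal outside the planted blocks and
    family-minimal (drawn from low-minimum families) inside them.

    ``blocks`` are 1-based closed codon intervals.  With the default human
    table the in-block adaptiveness sits near 20% and everything else at
    100%, so cluster detection has unambiguous ground truth.
    """
    adapt = adapt or relative_adaptiveness(load_usage_table())
    for start, end in blocks:
        if not 1 <= start <= end <= n_codons:
            raise GeneratorSpecError(f"block ({start}, {end}) outside 1..{n_codons}")
    rng = np.random.default_rng(seed)
    by_aa: dict[str, list[tuple[str, float]]] = {}
    from .codons import _codon_to_aa  # genetic-code mapping shared with codons

    for codon, a in _codon_to_aa(adapt.genetic_code_id).items():
        if a is not None:
            by_aa.setdefault(a, []).append((codon, adapt.values[codon]))
    max_codon = {a: max(cs, key=lambda cv: cv[1])[0] for a, cs in by_aa.items()}
    min_codon = {a: min(cs, key=lambda cv: cv[1])[0] for a, cs in by_aa.items()}
    rare_aas = [a for a, cs in by_aa.items() if min(v for _, v in cs) <= 30.0]
    in_block = np.zeros(n_codons, dtype=bool)
    for start, end in blocks:
        in_block[start - 1 : end] = True
    codons = []
    common_aas = sorted(by_aa)
    for i in range(n_codons):
        if i == 0:
            codons.append("ATG")
        elif in_block[i]:
            codons.append(min_codon[rare_aas[int(rng.integers(0, len(rare_aas)))]])
        else:
            codons.append(max_codon[common_aas[int(rng.integers(0, len(common_aas)))]])
    sequence = "".join(codons) + ("TAA" if include_stop else "")
    manifest = {
        "n_codons": n_codons,
        "blocks": [list(b) for b in blocks],
        "seed": seed,
        "include_stop": include_stop,
    }
    return CdsSim(sequence=sequence, manifest=manifest)


# ---------------------------------------------------------------------------
# trajectories


def helical_reference(
    n_residues: int = 169, atoms: str = "calpha"
) -> StructureFrame:
    """An ideal alpha-helical dummy chain (rise 1.5 A, 100 deg/residue).

    ``atoms='backbone'`` adds N, C and O atoms at fixed offsets around each
    alpha carbon; the geometry is regular, not stereochemically refined.
    """
    rise, twist, radius = 1.5, math.radians(100.0), 2.3
    names, resids, elements, masses, coords, resnames = [], [], [], [], [], []
    atom_spec = {
        "calpha": [("CA", "C", 12.011, np.zeros(3))],
        "backbone": [
            ("N", "N", 14.007, np.array([-0.8, 0.6, -0.6])),
            ("CA", "C", 12.011, np.zeros(3)),
            ("C", "C", 12.011, np.array([0.9, 0.4, 0.7])),
            ("O", "O", 15.999, np.array([1.4, -0.5, 1.2])),
        ],
    }
    if atoms not in atom_spec:
        raise GeneratorSpecError(f"unknown atom set {atoms!r}")
    for r in range(1, n_residues + 1):
        theta = twist * (r - 1)
        ca = np.array([radius * math.cos(theta), radius * math.sin(theta), rise * (r - 1)])
        for name, element, mass, offset in atom_spec[atoms]:
            names.append(name)
            resids.append(r)
            elements.append(element)
            masses.append(mass)
            coords.append(ca + offset)
            resnames.append("ALA")
    return StructureFrame(
        atom_names=tuple(names),
        residue_ids=np.array(resids),
        elements=tuple(elements),
        masses=np.array(masses),
        coords=np.array(coords),
        time_ps=0.0,
        residue_names=tuple(resnames),
    )


@dataclass
class TrajectorySim:
    """Reference + rigid motion + Gaussian fluctuations, with truth sigma."""

    trajectory: Trajectory
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        from .traj import write_multimodel_pdb

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_multimodel_pdb(self.trajectory, outdir / "trajectory.pdb")
        _write_manifest(outdir, self.manifest)


def gen_trajectory(
    reference: StructureFrame | None = None,
    n_frames: int = 400,
    sigma: float | Sequence[float] = 0.5,
    seed: int = 0,
    dt_ps: float = 25.0,
    rigid_motion: bool = True,
    max_rotation_deg: float = 20.0,
    max_translation: float = 5.0,
) -> TrajectorySim:
    """Frames = rigid_motion(t) applied to (reference + Gaussian noise).

    ``sigma`` is the per-coordinate fluctuation SD in angstroms, either a
    scalar or one value per residue; rigid motion draws a random rotation
    (axis uniform, angle uniform up to ``max_rotation_deg``) and
    translation per frame.  Snapshot spacing defaults to 25 ps.
    """
    from scipy.spatial.transform import Rotation

    reference = reference if reference is not None else helical_reference()
    rng = np.random.default_rng(seed)
    resids = reference.residue_ids
    unique_res = np.unique(resids)
    sigma_arr = np.asarray(sigma, dtype=float)
    if sigma_arr.ndim == 0:
        per_res = np.full(unique_res.size, float(sigma_arr))
    elif sigma_arr.size == unique_res.size:
        per_res = sigma_arr
    else:
        raise GeneratorSpecError(
            f"sigma length {sigma_arr.size} != residue count {unique_res.size}"
        )
    if np.any(per_res < 0):
        raise GeneratorSpecError("negative fluctuation amplitude")
    res_index = {r: i for i, r in enumerate(unique_res.tolist())}
    atom_sigma = np.array([per_res[res_index[int(r)]] for r in resids])
    frames = []
    for i in range(n_frames):
        noise = rng.normal(0.0, 1.0, size=reference.coords.shape) * atom_sigma[:, None]
        coords = reference.coords + noise
        if rigid_motion:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = math.radians(rng.uniform(0.0, max_rotation_deg))
            rot = Rotation.from_rotvec(axis * angle).as_matrix()
            shift = rng.uniform(-max_translation, max_translation, size=3)
            coords = coords @ rot.T + shift
        frames.append(
            StructureFrame(
                atom_names=reference.atom_names,
                residue_ids=reference.residue_ids,
                elements=reference.elements,
                masses=reference.masses,
                coords=coords,
                time_ps=i * dt_ps,
                residue_names=reference.residue_names,
            )
        )
    manifest = {
        "n_frames": n_frames,
        "seed": seed,
        "dt_ps": dt_ps,
        "rigid_motion": rigid_motion,
        "sigma_per_residue": per_res.tolist(),
        "residues": unique_res.tolist(),
    }
    return TrajectorySim(trajectory=Trajectory(frames), manifest=manifest)


# ---------------------------------------------------------------------------
# chase series


@dataclass
class ChaseSim:
    """Triplicate chase densitometry with known half-life."""

    points: list[ChaseTimepoint]
    manifest: dict

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "replicate": p.replicate,
                    "time_h": p.time_h,
                    "target_density": p.target_density,
                    "loading_density": p.loading_density,
                }
                for p in self.points
            ]
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table().to_csv(outdir / "chase.tsv", sep="\t", index=False)
        _write_manifest(outdir, self.manifest)


def gen_chase(
    half_life_h: float = 30.0,
    times: Sequence[float] = (0.0, 4.0, 8.0, 16.0, 24.0),
    n_replicates: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> ChaseSim:
    """First-order decay sampled as densitometry with lognormal noise.

    target = loading * 100 * exp(-t ln2 / half_life) * lognormal; an
    infinite half-life gives a flat (non-decaying) series.  ``noise_cv``
    is the coefficient of variation of the multiplicative noise.
    """
    if half_life_h <= 0:
        raise GeneratorSpecError(f"half-life must be positive, got {half_life_h}")
    if 0.0 not in times:
        raise GeneratorSpecError("time grid must include t = 0")
    if noise_cv < 0:
        raise GeneratorSpecError("negative noise CV")
    rng = np.random.default_rng(seed)
    log_sd = math.sqrt(math.log(1.0 + noise_cv**2))
    k = 0.0 if math.isinf(half_life_h) else math.log(2) / half_life_h
    points = []
    for r in range(1, n_replicates + 1):
        for t in times:
            loading = float(rng.uniform(800.0, 1200.0))
            frac = math.exp(-k * t)
            noise = float(rng.lognormal(0.0, log_sd)) if noise_cv > 0 else 1.0
            points.append(
                ChaseTimepoint(
                    time_h=float(t),
                    target_density=loading * 100.0 * frac * noise,
                    loading_density=loading,
                    replicate=f"r{r}",
                )
            )
    manifest = {
        "half_life_h": half_life_h if math.isfinite(half_life_h) else None,
        "k_per_h": k,
        "times": list(times),
        "n_replicates": n_replicates,
        "noise_cv": noise_cv,
        "seed": seed,
    }
    return ChaseSim(points=points, manifest=manifest)
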