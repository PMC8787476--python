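"""End-to-end orchestration: config, the structural-phylogenetics run and the
single-structure annotation report.

Everything is deterministic given (config, seed): all randomness is funneled
through the explicit seed, and outputs are plain CSV/JSON/Newick.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coiled_coil, interactions, motif_annotation, structure_io, struct_phylo


@dataclass
class RunConfig:
    """Module parameters with defaults matching each analysis convention."""

    salt_bridge_cutoff: float = 4.0
    contact_cutoff: float = 4.5
    contact_min_pairs: int = 10
    bin_width: float = 4.0
    stripe_net: float = -2.0
    flank_net: float = 2.0
    ion_cutoff: float = 3.5
    ion_min_donors: int = 3
    theta: float = struct_phylo.THETA
    alpha: float = struct_phylo.ALPHA
    resolution_cutoff: float = struct_phylo.RESOLUTION_CUTOFF
    linkage: str = "upgma"
    normalized_distance: bool = False
    seed: int = 0
    outdir: str = "."

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def core_segments(model, chain_ids: list[str] | None = None):
    """Longest helix segment per chain - the HR1 core of a bundle."""
    segments = coiled_coil.assign_helices(model)
    best: dict[str, object] = {}
    for seg in segments:
        if chain_ids and seg.chain_id not in chain_ids:
            continue
        if seg.chain_id not in best or len(seg) > len(best[seg.chain_id]):
            best[seg.chain_id] = seg
    return [best[k] for k in sorted(best)]


def run_phylo_pipeline(
    domains: list[struct_phylo.StutterAnchoredDomain],
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """All-vs-all alignment, Z-derived distances and dendrogram for a set of
    stutter-anchored domains; optionally writes distance CSV, Newick and the
    per-pair report."""
    config = config or RunConfig()
    if len(domains) < 3:
        raise ValueError("need at least 3 structures after filtering")
    dm, report = struct_phylo.all_vs_all(
        domains, seed=config.seed, normalized=config.normalized_distance,
        theta=config.theta, alpha=config.alpha,
    )
    tree = struct_phylo.build_dendrogram(dm, method=config.linkage)
    newick = struct_phylo.write_newick(tree)
    out = {"distance_matrix": dm, "tree": tree, "newick": newick, "report": report}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dm.to_frame().to_csv(outdir / "distances.csv")
        (outdir / "tree.nwk").write_text(newick)
        report.to_csv(outdir / "alignments.csv", index=False)
    return out


def simulate_lineage_recovery(
    n_replicates: int = 20,
    seed: int = 0,
    cr_lengths: tuple[int, ...] = (3, 14, 28),
    per_family: int = 3,
    noise: float = 0.3,
) -> list[bool]:
    """Scaled lineage-recovery simulation: families of protomers differing in
    chain-reversal loop length (the lineage driver), clustered by the
    Z-derived structural distance.

    For each replicate, builds ``per_family`` noisy protomers per family,
    runs the all-vs-all alignment with the normalized distance, cuts the UPGMA
    dendrogram into ``len(cr_lengths)`` clusters and records whether the cut
    reproduces family membership exactly.
    """
    from .synthetic_data import make_protomer

    results = []
    for rep in range(n_replicates):
        domains, family = [], {}
        for f, cr_len in enumerate(cr_lengths):
            for r in range(per_family):
                dom = make_protomer(
                    f"F{f}S{r}", cr_len, noise=noise,
                    seed=seed * 10_000 + rep * 100 + f * 10 + r,
                )
                domains.append(dom)
                family[dom.id] = f
        dm, _ = struct_phylo.all_vs_all(domains, seed=seed + rep, normalized=True)
        cut = struct_phylo.build_dendrogram(dm).cut(len(cr_lengths))
        clusters: dict[int, set[int]] = {}
        for label, cl in cut.items():
            clusters.setdefault(cl, set()).add(family[label])
        results.append(
            len(clusters) == len(cr_lengths)
            and all(len(v) == 1 for v in clusters.values())
        )
    return results


def run_structure_report(model, config: RunConfig | None = None,
                         trimer_chains: list[str] | None = None) -> dict:
    """Combined annotation of one structure: regions, register, stutters,
    bridges, stripe and ion sites, as a JSON-serializable dict.

    ``trimer_chains`` restricts axis/stripe analysis to one bundle (e.g. the
    first trimer of a two-trimer crystal form).
    """
    config = config or RunConfig()
    report: dict = {"id": model.id}

    chain0 = model.chains[0].chain_id
    seq, num_map = structure_io.extract_sequence(model, chain0)
    start = num_map[1]
    hits = motif_annotation.find_cx6cc(seq, start)
    report["cx6cc"] = hits
    if len(hits) == 1:
        regions = motif_annotation.annotate_regions(seq, hits[0], start)
        report["regions"] = {r.name: (r.start, r.end) for r in regions}

    segs = core_segments(model, trimer_chains)
    stutters: list[tuple[int, int]] = []
    axis = None
    if len(segs) >= 2:
        axis = coiled_coil.fit_bundle_axis(segs)
        assignments = coiled_coil.assign_heptad_register(segs, axis)
        report["register"] = {
            a.chain_id: {"numbers": a.numbers, "letters": a.letters}
            for a in assignments
        }
        stutters = sorted({s for a in assignments for s in a.stutter_spans})
    report["stutters"] = stutters

    bridges = interactions.detect_salt_bridges(model, cutoff=config.salt_bridge_cutoff)
    report["salt_bridges"] = [
        {"acid": b.acid, "base": b.base, "distance": round(b.distance, 2),
         "interchain": b.interchain}
        for b in bridges
    ]
    networks = interactions.bridge_networks(bridges)
    report["triads"] = [sorted(n.residues) for n in networks if n.is_triad]

    if axis is not None:
        sub = model
        if trimer_chains:
            sub = type(model)(id=model.id,
                              chains=[c for c in model.chains
                                      if c.chain_id in trimer_chains],
                              hetero=model.hetero)
        profile = interactions.axial_charge_profile(sub, axis, config.bin_width)
        stripe = interactions.detect_anion_stripe(
            profile, stripe_net=config.stripe_net, flank_net=config.flank_net)
        if stripe is not None:
            report["anion_stripe"] = {
                "members": sorted({m[1] for m in stripe.members}),
                "net": stripe.total_net,
                "flank_above": sorted({m[1] for b in stripe.flank_above
                                       for m in b.basic}),
                "flank_below": sorted({m[1] for b in stripe.flank_below
                                       for m in b.basic}),
            }
        else:
            report["anion_stripe"] = None
        ions = interactions.detect_ion_coordination(
            model, "Cl", cutoff=config.ion_cutoff,
            min_donors=config.ion_min_donors, axis=axis)
        report["ion_sites"] = [
            {"element": s.element, "n_donors": s.n_donors,
             "donor_residues": sorted({(d[0], d[1], d[2]) for d in s.donors}),
             "axial_offset": None if s.axial_offset is None
             else round(s.axial_offset, 2)}
            for s in ions
        ]
    return report
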