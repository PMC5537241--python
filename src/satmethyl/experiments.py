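"""End-to-end study emulations: monomer library, methylation, digestion.

Each experiment generates synthetic data under the conditions of the
satellite-DNA study design this package models — cloned ~315 bp monomers from
three related species, Sanger-cloned bisulfite reads from both strands, an
unmethylated PCR-product conversion control, and restriction digestion of
tandem arrays — runs the analysis pipeline on it, and returns the headline
quantities.  Replicated experiments report Monte-Carlo means over independent
simulated studies.

Study conditions emulated (fixed here, not tunable per run):

* monomer length 315 bp, G+C target 0.4405;
* three species with 39 / 21 / 11 cloned monomers and intraspecific
  diversities ~0.0294 / 0.0340 / 0.0290 (substitution rates solved from the
  expected pairwise-divergence formula);
* conserved domains at positions 41-89 and 199-232 and four 15 bp variable
  regions, with the base rate re-calibrated so overall diversity is preserved;
* restriction motifs carried by the ancestral repeat: one GGCC and one TCGA
  in conserved domains, one CAGCTG in a variable region, three CCGG;
* per-context methylation rates CG 5.65% > CHH 2.69% > CHG 1.79%, bisulfite
  conversion efficiency 0.987, 33 direct + 26 complementary clone reads;
* for spatial analyses, methylation hot blocks at 60-89 and 209-221 (x3)
  nested inside the conserved domains.
"""

from __future__ import annotations

import numpy as np

from .digestor import ENZYMES, digest, find_sites
from .diversity import nucleotide_diversity, sliding_window_pi
from .methylation import (
    call_methylation,
    correlate_tracks,
    estimate_conversion_efficiency,
    sliding_window_methylation,
    summarize_by_context,
)
from .seqio import SeqRecord, build_consensus, gc_content
from .synth import (
    FamilyConfig,
    MethylationConfig,
    assign_methylation,
    generate_family,
    make_control_reads,
    make_reads,
    tandem_array,
)

CONSERVED_BLOCKS = ((41, 89), (199, 232))
VARIABLE_BLOCKS = ((10, 24), (110, 124), (160, 174), (245, 259))
HOT_BLOCKS = ((60, 89), (209, 221))
ANCESTRAL_MOTIFS = (
    (45, "GGCC"),    # HaeIII, conserved domain -> clean monomer ladder
    (70, "CCGG"),    # HpaII/MspI x3
    (110, "CAGCTG"),  # PvuII, variable region -> partially lost site
    (150, "CCGG"),
    (190, "CCGG"),
    (205, "TCGA"),   # TaqI, conserved domain
)
SPECIES_PI = {"SSU": 0.0294, "SSO": 0.0340, "MST": 0.0290}
SPECIES_N = {"SSU": 39, "SSO": 21, "MST": 11}


def expected_pairwise_divergence(p: float, cfg: FamilyConfig | None = None) -> float:
    """Expected p-distance between two monomers mutated at per-site rate p.

    Both lineages mutate independently from the ancestor; coincident hits
    land on the same alternative with probability 1/3.  With a config, the
    per-site rate is modulated by its conserved/variable block factors and
    the expectation averaged over sites.
    """
    def d(q: float) -> float:
        return 2 * q * (1 - q) + (2 / 3) * q * q

    if cfg is None:
        return d(p)
    factors = [cfg.site_factor(pos) for pos in range(1, cfg.monomer_length + 1)]
    return float(np.mean([d(min(p * f, 1.0)) for f in factors]))


def substitution_rate_for_pi(
    target_pi: float, cfg: FamilyConfig | None = None
) -> float:
    """Invert the expected pairwise divergence for the per-site rate (bisection)."""
    lo, hi = 0.0, 0.5
    for _ in range(60):
        mid = (lo + hi) / 2
        if expected_pairwise_divergence(mid, cfg) < target_pi:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def study_family_config(seed: int, structured: bool = True) -> FamilyConfig:
    """Three-species monomer library at the study's diversity levels."""
    template = FamilyConfig(
        conserved_blocks=CONSERVED_BLOCKS if structured else (),
        variable_blocks=VARIABLE_BLOCKS if structured else (),
        ancestral_motifs=ANCESTRAL_MOTIFS,
    )
    rates = {
        sp: substitution_rate_for_pi(pi, template) for sp, pi in SPECIES_PI.items()
    }
    # the planted motifs are GC-rich; lower the random-background target so
    # the whole monomer still lands on the study's G+C content
    length = template.monomer_length
    motif_bases = sum(len(m) for _, m in ANCESTRAL_MOTIFS)
    motif_gc = sum(m.count("G") + m.count("C") for _, m in ANCESTRAL_MOTIFS)
    background_gc = (0.4405 * length - motif_gc) / (length - motif_bases)
    return FamilyConfig(
        n_monomers=dict(SPECIES_N),
        per_site_substitution_prob=rates,
        gc_target=background_gc,
        conserved_blocks=template.conserved_blocks,
        variable_blocks=template.variable_blocks,
        ancestral_motifs=ANCESTRAL_MOTIFS,
        exclusive_motifs=True,
        exact_composition=True,
        seed=seed,
    )


def study_methylation_config(seed: int, spatial: bool = False) -> MethylationConfig:
    return MethylationConfig(
        hot_blocks=HOT_BLOCKS if spatial else (),
        seed=seed,
    )


def _spawn(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, deterministic in `seed`."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def family_experiment(seed: int, n_replicates: int = 10) -> dict:
    """Monomer-library characterization: Pi per species and pooled, G+C, lengths.

    Returns Monte-Carlo means over replicate simulated libraries, plus the
    last replicate's objects for downstream use.
    """
    acc: dict[str, list[float]] = {k: [] for k in
                                   ["pi_SSU", "pi_SSO", "pi_MST", "pi_pooled",
                                    "gc_pct", "full_length_SSU"]}
    last = None
    for child in _spawn(seed, n_replicates):
        cfg = study_family_config(child)
        ancestral, monomers = generate_family(cfg)
        ssu = monomers.subset_species("SSU")
        acc["pi_SSU"].append(nucleotide_diversity(ssu))
        acc["pi_SSO"].append(nucleotide_diversity(monomers.subset_species("SSO")))
        acc["pi_MST"].append(nucleotide_diversity(monomers.subset_species("MST")))
        acc["pi_pooled"].append(nucleotide_diversity(monomers))
        acc["gc_pct"].append(100 * gc_content(list(ssu)))
        acc["full_length_SSU"].append(
            sum(1 for r in ssu if "-" not in r.sequence)
        )
        last = (cfg, ancestral, monomers)
    out = {k: float(np.mean(v)) for k, v in acc.items()}
    out["consensus_width"] = build_consensus(last[2]).width
    out["_last"] = last
    return out


def methylation_experiment(seed: int, n_replicates: int = 20) -> dict:
    """Bisulfite profiling at study read depth: context table and efficiency.

    Single-species default family (no spatial blocks), 33 direct + 26
    complementary clone reads, 30 unmethylated controls; calls are
    mutation-bias normalized and corrected with the efficiency estimated from
    the controls; the summary is observation-weighted.
    """
    rows: list[dict] = []
    effs: list[float] = []
    for child in _spawn(seed + 1, n_replicates):
        cfg = FamilyConfig(seed=child)
        mcfg = study_methylation_config(child + 1)
        ancestral, monomers = generate_family(cfg)
        maps = assign_methylation(monomers, mcfg)
        reads = make_reads(monomers, maps, mcfg)
        cons = build_consensus(monomers)
        controls = make_control_reads(
            ancestral, mcfg.conversion_efficiency, 30, seed=child + 2
        )
        eff = estimate_conversion_efficiency(
            controls, SeqRecord("ref", cons.consensus)
        )
        effs.append(eff)
        calls = call_methylation(monomers, reads, cons, conversion_efficiency=eff)
        pct = summarize_by_context(calls).percent()
        rows.append(
            {
                "overall_pct": pct.loc["All C", "both"],
                "cg_pct": pct.loc["CG", "both"],
                "chg_pct": pct.loc["CHG", "both"],
                "chh_pct": pct.loc["CHH", "both"],
                "direct_pct": pct.loc["All C", "direct"],
                "complementary_pct": pct.loc["All C", "complementary"],
            }
        )
    out = {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}
    out["conversion_efficiency_pct"] = float(100 * np.mean(effs))
    out["n_reads"] = 33 + 26
    return out


def spatial_experiment(seed: int, n_replicates: int = 10) -> dict:
    """Window tracks and the methylation-diversity Spearman correlation.

    Families carry the conserved/variable mosaic; methylation is elevated x3
    in hot blocks nested inside conserved domains, reproducing the study
    design in which high-methylation segments overlap conserved ones, hence a
    negative methylation-diversity correlation.
    """
    rho_d, rho_b, overlaps = [], [], []
    for child in _spawn(seed + 2, n_replicates):
        cfg = study_family_config(child)
        mcfg = study_methylation_config(child + 1, spatial=True)
        _, monomers = generate_family(cfg)
        ssu = monomers.subset_species("SSU")
        maps = assign_methylation(ssu, mcfg)
        reads = make_reads(ssu, maps, mcfg)
        cons = build_consensus(ssu)
        calls = call_methylation(ssu, reads, cons)
        pi_track = sliding_window_pi(ssu)
        meth_d = sliding_window_methylation(
            calls, strand="direct", width=cons.width
        )
        meth_b = sliding_window_methylation(calls, strand="both", width=cons.width)
        rho_d.append(correlate_tracks(meth_d, pi_track)[0])
        rho_b.append(correlate_tracks(meth_b, pi_track)[0])
        # fraction of above-threshold methylation windows inside hot blocks
        hi = meth_b.mean + 2 * meth_b.sd
        flagged = [
            s
            for s, v in zip(meth_b.starts, meth_b.values)
            if np.isfinite(v) and v > hi
        ]
        if flagged:
            inside = [
                s
                for s in flagged
                if any(
                    not (s + meth_b.window_width - 1 < a or s > b)
                    for a, b in HOT_BLOCKS
                )
            ]
            overlaps.append(len(inside) / len(flagged))
    return {
        "spearman_rho_direct": float(np.mean(rho_d)),
        "spearman_rho_both": float(np.mean(rho_b)),
        "high_meth_windows_in_hot_blocks": float(np.mean(overlaps)),
        "n_windows": 315 - 10 + 1,
    }


def digestion_experiment(seed: int) -> dict:
    """Restriction-assay emulation on a tandem array of study-like monomers.

    HaeIII (conserved site) should give a near-pure monomer ladder; PvuII
    (variable-region site) leaves longer multimers; HpaII/MspI share CCGG
    targets and differ only through methylation.
    """
    cfg = study_family_config(_spawn(seed + 3, 1)[0])
    _, monomers = generate_family(cfg)
    ssu = monomers.subset_species("SSU")
    mcfg = study_methylation_config(cfg.seed + 1, spatial=True)
    maps = assign_methylation(ssu, mcfg)
    # a long array: every cloned monomer repeated in tandem, 4 copies
    ids = [r.id for r in ssu]
    from .seqio import MonomerAlignment

    stacked = MonomerAlignment(
        tuple(
            SeqRecord(f"{r.id}.{k}", r.sequence, r.species)
            for k in range(4)
            for r in ssu
        )
    )
    stacked_maps = {
        f"{rid}.{k}": maps[rid] for k in range(4) for rid in ids
    }
    array = tandem_array(stacked, stacked_maps)
    cons = build_consensus(ssu)

    unit = cons.width  # nominal monomer unit (deletions shave a few bp)
    hae = digest(array, ENZYMES["HaeIII"], seed=seed, unit=unit)
    pvu = digest(array, ENZYMES["PvuII"], seed=seed, unit=unit)
    hpa = digest(array, ENZYMES["HpaII"], seed=seed, unit=unit)
    msp = digest(array, ENZYMES["MspI"], seed=seed, unit=unit)
    hae_ladder = hae.ladder(tolerance=2)
    consensus_array = tandem_array(
        MonomerAlignment(
            (SeqRecord("c1", cons.consensus), SeqRecord("c2", cons.consensus))
        ),
        circular=False,
    )
    n_ccgg = len(
        [s for s in find_sites(consensus_array, ENZYMES["MspI"]) if s < cons.width]
    )
    mean_multimer = lambda spec: float(
        np.mean([length / spec.unit for length in spec.lengths])
    )
    return {
        "ccgg_sites_per_monomer": n_ccgg,
        "haeiii_monomer_band_fraction": hae_ladder.get(1, 0) / len(hae.lengths),
        "haeiii_mean_multimer": mean_multimer(hae),
        "pvuii_mean_multimer": mean_multimer(pvu),
        "hpaii_fragments": len(hpa.lengths),
        "mspi_fragments": len(msp.lengths),
        "array_length_bp": len(array),
        "_spectra": {"HaeIII": hae, "PvuII": pvu, "HpaII": hpa, "MspI": msp},
    }
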