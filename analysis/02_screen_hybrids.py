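"""Heterozygosity screen and ancestry of the F1 workers.

The hybrid workers sit an order of magnitude above every non-hybrid in
heterozygous-site proportion, and their maternal-source ancestry averages
~0.5, the F1 signature.  Writes the per-individual screen table.
"""

import pandas as pd

from common import RESULTS, study_cohort
from xenopop import hybrid_screen as hs
from xenopop.variant_store import filter_sites


def main() -> None:
    sim = study_cohort()
    panel = filter_sites(sim.cohort)
    adults = [m.individual_id for m in panel.individuals if m.caste in ("queen", "worker", "male")]
    profiles = hs.het_profiles(panel, adults)
    calls = {c.individual_id: c for c in hs.classify_f1(profiles)}
    f1 = [p.individual_id for p in profiles if calls[p.individual_id].is_f1]

    meta = {m.individual_id: m for m in panel.individuals}
    mat_src = [i for i in adults if i not in f1 and meta[i].nominal_species == "ibericus"]
    pat_src = [i for i in adults if i not in f1 and meta[i].nominal_species == "structor"]
    freqs = (hs.allele_frequencies(panel, mat_src), hs.allele_frequencies(panel, pat_src))
    q = {i: hs.estimate_ancestry(panel, i, freqs).q_maternal for i in f1}

    rows = pd.DataFrame(
        {
            "individual_id": [p.individual_id for p in profiles],
            "het_sites": [p.het_sites for p in profiles],
            "panel_size": [p.panel_size for p in profiles],
            "het_proportion": [p.het_proportion for p in profiles],
            "is_f1": [calls[p.individual_id].is_f1 for p in profiles],
            "q_maternal": [q.get(p.individual_id) for p in profiles],
        }
    )
    rows.to_csv(RESULTS / "hybrid_screen.tsv", sep="\t", index=False)

    het_f1 = rows.loc[rows.is_f1, "het_proportion"]
    het_other = rows.loc[~rows.is_f1, "het_proportion"]
    p = hs.compare_groups(het_f1, het_other)
    print(f"panel: {panel.n_sites} polymorphic sites")
    print(f"F1 workers flagged: {len(f1)}")
    print(
        f"mean heterozygosity {het_f1.mean():.3f} (F1) vs {het_other.mean():.3f} "
        f"(non-hybrid), rank-sum p = {p:.3g}"
    )
    print(f"mean maternal ancestry of F1 workers: {rows.q_maternal.mean():.3f}")


if __name__ == "__main__":
    main()
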