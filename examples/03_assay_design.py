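"""Design scheduled PRM methods from simulated chromatograms.

Transitions are filtered on area, signal-to-background, relative area,
correlation and width; precursors with three or more qualifying
transitions are accepted, scheduled into 2-minute windows and packed into
methods that keep every target at >= 7 points per peak.
"""

from prmkit import assaydesign as ad, features, simulate
from prmkit.simulate import SimConfig

config = SimConfig(seed=4, n_peptides=30, n_replicates=3)
traces, truth = simulate.sim_chromatograms(config)

candidates = []
for row in truth.itertuples(index=False):
    group = {k[1]: v for k, v in traces.items() if k[0] == row.peptide and k[2] == 0}
    feats = features.extract_features(group, (row.rt - 1.5 * row.fwhm, row.rt + 1.5 * row.fwhm))
    candidates.append(
        ad.TargetCandidate(
            precursor_id=row.peptide, sequence="PEPTIDEK", charge=2, label="light",
            precursor_mz=500.0, expected_rt=row.rt, peak_width=row.fwhm,
            window=(row.rt - 60, row.rt + 60), transitions=tuple(feats),
        )
    )

accepted, rejected = ad.accept_precursors(candidates, ad.FilterCriteria())
print(f"accepted {len(accepted)}/{len(candidates)} precursors; rejected: {len(rejected)}")

timing = ad.TimingModel()  # 125 kDa/s scan-out, 5 ms overhead, goal 7 points/peak
result = ad.split_assays(ad.schedule_windows(accepted, 120.0), timing)
print(f"scheduled into {len(result.methods)} method(s)")
for i, m in enumerate(result.methods):
    print(
        f"  method {i}: {len(m.targets)} targets, "
        f"worst cycle {m.worst_cycle_time() * 1e3:.1f} ms, "
        f"min points/peak {min(ad.points_per_peak(m, t) for t in m.targets):.1f}"
    )

target_list = ad.export_target_list(result.methods[0])
print(target_list.head().to_string(index=False))
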