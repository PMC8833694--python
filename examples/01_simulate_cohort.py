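"""Generate a synthetic paired-design cohort and write it to disk.

Eight subjects at the pilot-study scale: five tumor-injected (involved
left nodes) and three control-injected, including the motion-corrupted
control-CEUS case and the imaging-positive/pathology-negative case.
"""

from lnscore import CohortSpec, generate_cohort, write_cohort

spec = CohortSpec(seed=42)
subjects = generate_cohort(spec)
outdir = write_cohort(subjects, "scratch/example_cohort", spec.to_dict())

print(f"wrote {2 * len(subjects)} nodes to {outdir}/")
for s in subjects:
    truth = s.left.truth
    print(
        f"{s.subject_id:6s} {s.group:17s} left volume {truth['volume_mm3']:6.2f} mm^3, "
        f"L/W {truth['lw_ratio']:.2f}, TTP {truth['ttp_s']:.2f} s, "
        f"pathology {'positive' if s.pathology_positive_left else 'negative'}"
    )
# Tumor-group left nodes are ~10x larger, rounder and slower to enhance
# than their internal controls; that contrast is what the scoring detects.
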