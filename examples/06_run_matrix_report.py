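"""Run a small polymers x modes x replicates matrix and print the report.

Planted mode (no dynamics) keeps this instant; switch planted=False for
real steered runs.  The report mirrors the figure structure of the study:
contacts, hydrogen bonds/bridges, energy proportions, pose proportions.
"""

from polysurf.dynamics import END_GRAFTED, U_SHAPED
from polysurf.pipeline import RunConfig, report, run_matrix

cfg = RunConfig.quick(
    polymers=("cellulose", "PAM", "HPAM"),
    modes=(END_GRAFTED, U_SHAPED),
    replicates=2,
    planted=True,
)
summary = run_matrix(cfg)
print(summary[["polymer", "mode", "replicate", "seed", "status",
               "mean_contacts", "mean_hbonds", "prop_end_grafted",
               "prop_u_shaped"]].to_string(index=False))
print()
print(report(summary))

# Every row carries polymer, mode, replicate, seed and package version;
# planted proportions are exact (1.0 for the planted pose).
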