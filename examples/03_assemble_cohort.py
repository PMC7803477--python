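"""Generate a synthetic cohort and assemble paired activity observations.

Every observation is a 7-day window recalled on the IPAQ for which the same
7 days have adequate device data; BMI and covariates are attached by the
time-window rules (90 d for weight/BMI, 365 d for height and covariates).
"""

from actipair import GeneratorConfig, generate_cohort, observations_to_frame, pipeline

bundle = generate_cohort(GeneratorConfig(n_participants=60), seed=11)
print(
    f"generated {len(bundle.series)} device weeks for "
    f"{len(bundle.participant_meta)} participants "
    f"({len(bundle.ipaq_responses)} IPAQ responses)"
)

sets = pipeline.assemble(
    bundle.series,
    bundle.ipaq_responses,
    bundle.anthropometry,
    bundle.covariates,
    bundle.participant_meta,
)
print(
    f"comparative set: {len(sets.comparative)} first observations; "
    f"BMI set: {len(sets.bmi_all)} observations with BMI + complete covariates"
)

frame = observations_to_frame(sets.bmi_all)
cols = ["participant_id", "window_start", "season", "bmi",
        "fitbit_steps_per_day", "ipaq_met_h"]
print("\nfirst rows of the analysis table:")
print(frame[cols].head(5).to_string(index=False))
print("\nEach row pairs one device-measured week with the self-report "
      "recalling the same 7 days.")
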