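# Default opioid-overdose code set.
#
# Fatal: underlying cause of death in `underlying_cause_codes` (unintentional,
# self-harm, assault, or undetermined poisoning) together with at least one
# multiple-cause code matching a `t_codes` prefix (opioid poisoning agents),
# OR a death-certificate literal-text match on `literal_terms`.
# Non-fatal: any ED/inpatient diagnosis code matching `nonfatal_dx_prefixes`.
# Codes are compared after normalization (uppercase, dots removed), by prefix.
name: default_opioid_overdose
underlying_cause_codes:
  [X40, X41, X42, X43, X44, X60, X61, X62, X63, X64, X85, Y10, Y11, Y12, Y13, Y14]
t_codes: [T400, T401, T402, T403, T404, T406]
nonfatal_dx_prefixes: [T400, T401, T402, T403, T404, T406]
literal_terms:
  [heroin, fentanyl, opioid, opiate, oxycodone, hydrocodone, morphine, methadone]
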