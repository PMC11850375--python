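# Default relation-extraction schema.
#
# Hypothesis templates per relation ("{concept 1} leads to {concept 2}" is the
# canonical creates-template; the others are package defaults, replaceable by
# pointing the pipeline at another schema file). Admissibility is a cross
# product over argument types per direction; hypotheses for inadmissible type
# pairs are never generated (a disease cannot cause a point in time).
# Cue lists license the micro-relations AM/CR/EX; the AM and EX lists are the
# documented trigger inventories plus common inflections, the CR list is a
# package default built from explicit causal connectives.
threshold: 0.2
templates:
  AM:
    - "{concept 1} improves {concept 2}"
    - "{concept 1} ameliorates {concept 2}"
  CR:
    - "{concept 1} leads to {concept 2}"
  DG:
    - "{concept 1} is used to diagnose {concept 2}"
  EX:
    - "{concept 1} worsens {concept 2}"
  IAW:
    - "{concept 1} is associated with {concept 2}"
  IUF:
    - "{concept 1} is used for {concept 2}"
    - "{concept 1} is a treatment for {concept 2}"
  ITO:
    - "{concept 1} is the time of {concept 2}"
admissible:
  AM: {arg1: [TR, DR], arg2: [DI, SY]}
  CR: {arg1: [DI, SY, TR, DR], arg2: [DI, SY, TR, DR]}
  DG: {arg1: [TR, DR], arg2: [DI, SY]}
  EX: {arg1: [DI, SY, TR, DR], arg2: [DI, SY, TR, DR]}
  IAW: {arg1: [DI, SY, TR, DR], arg2: [DI, SY, TR, DR]}
  IUF: {arg1: [TR, DR], arg2: [DI, SY]}
  ITO: {arg1: [DATE, DURATION], arg2: [DI, SY, TR, DR]}
cues:
  AM: [improve, improves, improved, improving, ameliorate, ameliorates, amelioration,
       decrease, decreases, decreased, reduce, reduces, reduced]
  CR: [causes, caused, "leads to", "led to", "due to", "results in", "resulting in",
       "because of"]
  EX: [exacerbate, exacerbates, exacerbated, worsen, worsens, worsened, worse]
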