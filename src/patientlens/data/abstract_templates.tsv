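# target	pattern	questions (|| separated; empty for grounded targets)	threshold
# The NEED hypothesis/question pair and the DIAGNOSIS "diagnosed."/"detected." patterns
# are the canonical inventory; the remaining rows are package defaults, fully
# replaceable by pointing the pipeline at another template file.
NEED	Someone needs something.	What is needed?	0.5
SUPPORT	Someone receives support.	What support is provided?||Who provides support?	0.5
DIAGNOSIS	{entity} was diagnosed.		0.5
DIAGNOSIS	{entity} was detected.		0.5
MISDIAGNOSIS	{entity} was misdiagnosed.		0.5
MISDIAGNOSIS	{entity} was missed.		0.5
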