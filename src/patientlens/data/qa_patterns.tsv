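# Reference question-answering pattern table: question <TAB> regex with a named group "answer".
# Adequate for fixtures and offline tests; a reading-comprehension model backend
# is the intended production implementation of the answering contract.
What is needed?	\bin need of (?P<answer>.+?)(?=$|[,.;:!?]|\s+(?:is|are|was|were|has|have|had|but|and)\b)
What is needed?	\b(?:needs?|requires?|still need)\s(?P<answer>.+?)(?=$|[,.;:!?]|\s+(?:is|are|was|were|has|have|had|but|and)\b)
What support is provided?	\bsupport (?:from|by) (?P<answer>.+?)(?=$|[,.;:!?])
What support is provided?	\b(?:received|receives|offered|offers|provided|provides) (?P<answer>.+?)(?=$|[,.;:!?]|\s+(?:to|for)\b)
Who provides support?	\bsupport (?:from|by) (?P<answer>.+?)(?=$|[,.;:!?])
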