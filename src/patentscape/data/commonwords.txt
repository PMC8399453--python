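# Default common-word list: generic patent-prose words that carry no
# domain-specific context.  Seed entries only; override with your own file
# for a production analysis.  Entries are lemmatized on load, so inflected
# forms may be listed.
consists
contain
effect
enables
excellent
exhibit
good
main
method
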