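# Placeholder custom stopword tier.
# Conversational filler frequent in verbatim consultation speech transcripts
# but uninformative about the clinical chapter. Edit freely; behaviour of the
# removal pipeline, not this membership, is the tested contract.
yeah
yes
no
okay
ok
right
well
um
uh
erm
er
hmm
mm
oh
ah
like
know
think
mean
just
really
actually
basically
obviously
sort
kind
bit
thing
things
stuff
going
gonna
got
get
say
said
see
look
come
came
want
good
fine
thank
thanks
please
hello
bye
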