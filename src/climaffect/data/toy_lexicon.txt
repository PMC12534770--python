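# Demonstration category lexicon (synthetic; not derived from any licensed
# dictionary). One [category] per section, one entry per line, trailing *
# marks a stem matched by prefix.

[posemo]
good
happ*
love
nice
great
hope*
joy
calm
relief
warm

[negemo]
bad
sad*
fear*
angr*
hate
awful
worry
pain
gloom*
terrible

[anger]
angr*
hate
rage
furious
annoy*

[anxiety]
fear*
worry
anxious
nervous
panic

[sadness]
sad*
gloom*
cry
grief
miserable

[affiliation]
friend*
family
together
we
our
community
neighbor*
ally
team

[body]
body
skin
sweat*
head
heart
hands
sleep*

[feel]
feel*
touch*
hot
cold
burn*
numb

[article]
a
an
the

[preposition]
in
on
at
of
with
under
over

[ppron]
i
you
he
she
they
me
him
her
us
them

[ipron]
it
this
that
these
those
something

[auxverb]
is
are
was
were
be
have
has
do
does
will

[conj]
and
but
or
so
because
while

[adverb]
very
really
quite
too
almost
never
always

[negate]
no
not
none
cannot
without
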