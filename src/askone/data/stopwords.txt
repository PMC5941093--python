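# Bundled English stopword list (one token per line; '#' lines ignored).
# Tokens are matched after tokenization, i.e. lowercased with apostrophes
# removed, so contractions appear as e.g. "dont", "shes".
a
about
above
after
again
all
also
am
an
and
any
are
arent
as
at
be
because
been
before
being
below
between
both
but
by
can
cant
could
couldnt
did
didnt
do
does
doesnt
doing
dont
down
during
each
few
for
from
further
had
hadnt
has
hasnt
have
havent
having
he
hed
hell
her
here
hers
herself
hes
him
himself
his
how
i
id
if
ill
im
in
into
is
isnt
it
its
itself
ive
just
me
more
most
my
myself
no
nor
not
now
of
off
on
once
only
or
other
our
ours
ourselves
out
over
own
same
she
shed
shell
shes
should
shouldnt
so
some
such
than
that
thats
the
their
theirs
them
themselves
then
there
theres
these
they
theyd
theyll
theyre
theyve
this
those
through
to
too
under
until
up
very
was
wasnt
we
wed
well
were
werent
weve
what
whats
when
where
which
while
who
whom
whos
why
will
with
wont
would
wouldnt
you
youd
youll
your
youre
yours
yourself
yourselves
youve
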