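a
about
according
after
afternoon
again
ago
all
almost
also
although
am
ambulance
an
and
any
are
as
ask
asked
at
away
back
bad
be
because
become
bed
been
before
being
better
between
big
book
both
but
by
call
called
came
can
car
care
carry
change
checked
clear
close
cold
come
concern
could
day
days
dear
delay
developed
diagnosis
did
do
doctor
does
done
down
during
each
early
eat
end
enough
even
evening
ever
every
family
far
father
feel
feeling
felt
few
find
fine
first
five
following
for
found
four
from
full
function
further
gave
get
given
go
going
gone
good
got
great
had
happy
hard
has
have
he
head
help
her
here
high
him
his
home
hospital
hour
hours
house
how
husband
if
impaired
improve
improved
in
increase
increased
intended
into
is
it
its
just
keep
kept
know
large
last
later
leads
left
less
letter
life
like
little
live
long
look
low
made
make
man
many
may
me
men
might
mild
mind
miss
month
months
more
morning
most
mother
move
much
must
my
name
near
need
never
new
next
night
nil
no
nonspecific
normal
not
nothing
now
nowadays
number
of
off
old
on
once
one
only
open
or
other
otherwise
our
out
over
own
part
past
patient
people
perhaps
person
phone
place
plan
please
possible
present
problem
problems
protocol
put
query
quite
rather
reassured
recent
recently
recheck
report
rest
result
results
review
reviewed
right
road
said
same
saw
say
second
see
seeing
seems
seen
send
sent
set
severe
she
should
show
showed
shown
side
significant
since
sister
six
sleep
slight
small
so
some
soon
sorry
speak
spoke
start
started
state
statement
stay
still
stop
stopped
such
sure
take
taken
taking
talk
tell
ten
test
than
thank
that
the
their
them
then
there
these
they
thing
think
this
those
three
through
thursday
time
times
tired
to
today
told
tomorrow
took
try
turn
two
under
unit
until
unwell
up
upon
use
used
very
visit
wait
walk
want
was
water
way
we
week
weeks
well
went
were
what
when
where
which
while
who
whole
why
wife
will
with
within
woman
work
worse
would
year
years
yes
yesterday
yet
you
young
your
mg
ml
kg
mcg
od
bd
tds
qds
prn
stat
mr
mrs
ms
dr
prof
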