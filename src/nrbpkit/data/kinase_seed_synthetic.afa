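>invertebrate_0001 synthetic kinase-domain seed row
CLKAQNIDRYALCTKKAPGEPLEIMHIRHQDVMVHTSINQINGHHDKDVVTTCSDWCYRW
>invertebrate_0002 synthetic kinase-domain seed row
CLKAQNIDRYATCTKKAPHEPLEIMHIRLQDVMVHQVINFINGHYDKDPVTTCSDWYYKW
>invertebrate_0003 synthetic kinase-domain seed row
CLEAQNIDRYALCTKKCPHEPLEIMHIRLQDVMVHCSINQWNGHHDKYPQTTCTDWCFKW
>invertebrate_0004 synthetic kinase-domain seed row
CLEAQNIDRYALCTKKCPHEPLEIMHIRLQDVMVHCSINQWNGHHDKYPQTTCTDWCFKW
>P1_0001 synthetic kinase-domain seed row
CLEIQMIDRGALCQLKLPPEHLLIMHNTLADVMVHCSINQINWHHDKDPQFTCTDQCYKW
>P1_0002 synthetic kinase-domain seed row
CLEIQNIDRGALCQKKAPHEHLLIMHNTLADVMVHCSINQINEHLDKDPQETCTDQCYKW
>P1_0003 synthetic kinase-domain seed row
CLEIQNIDRGALCQKKAPHEHLLIMHNTLADVMVHCWINQINEHHDKDPQTTCTDNCYKW
>P1_0004 synthetic kinase-domain seed row
CLEIQNIDRGALCQKKAPHEHLLIMHNTLADVMVHCWINQINEHHDKDPQTTCTDNCYKW
>P2_0001 synthetic kinase-domain seed row
CVEAQNIDRQAYCAKKAPREPLLIMHIRLADEMVHCVIDQILCHKDLDQQTTSTDNCYKW
>P2_0002 synthetic kinase-domain seed row
CLEAQNIDRQAFCQKKAPREPLLIMHIRLADVMVHCTINQINCHKDKDPQTTCTDNCYKW
>P2_0003 synthetic kinase-domain seed row
CDEAQNIDREAFCQKKAPHEELLIMHIRLADVMVHCSINQINCHHDKDPQTTCTYNCYKW
>P2_0004 synthetic kinase-domain seed row
GDQAVNIDEEALCQVKKPHEELLIMHIRLADISVHCSWNKINMQHDKDFQRTCTFNYYKC
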