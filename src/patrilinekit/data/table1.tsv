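foundation_sire	subline	count	breed_or_registry	ht_label	remark
Koheilan Adjuze db	Piolun, 1934	8	Arabian Austria(1) Russia(5); Trakehner(2)	Ao-aA1a*
Koheilan Adjuze db	Jaszmak, 1928	3	Shagya Arabian(3)	Ao-aA1a*
Mahmoud Mirza db	Jussuf I, 1962	2	Shagya Arabian(2)	Ao-aA1a*
Old Jellabi Speckled	Dhahmaan Alawwal, 1938	3	Arabian Austria(2) Poland(1)	Ao-aA1a*
Zarif	Rex II 372, 1941	4	Fredriksborg Horse(4)	Ao-aA1a*
Zarif	Hermolin, 1937	2	Knabstrupper(2)	Ao-aA1a*
Zobeyni db	Mahruss II, 1893	1	Arabian Germany(1)	Ao-aA1a*
Ilderim db	Aquinor, 1951	3	Arabian Poland(3)	Ao-aA1a*
Ilderim db	Maharadscha, 1957	3	Trakehner(1); Warmblood(2)	Ao-aA1a4	subline-HT
Ilderim db	Doktryner, 1950	2	Arabian USA(1); Lewitzer(1)	Ta-b	incongruence
Saklawi I	Ansata Ibn Halima, 1958	8	Arabian Egypt(1) Qatar(3) Poland(2) Syria(1); Shagya Arabian(1)	Ao-aA1a1
Saklawi I	Aswan, 1958	5	Arabian Iran(1) Poland(1) Qatar(1) Russia(1); Shagya Arabian(1)	Ao-aA1a1
Saklawi I	Galal, 1959	4	Arabian Egypt(1) Germany(1); Shagya Arabian(2)	Ao-aA1a1
Saklawi I	Habdan Enzahi, 1952	6	Arabian Austria(1) Egypt(2) Iran(1) Poland(2)	Ao-aA1a1
Saklawi I	Morafic, 1952	9	Arabian Egypt(1) Iran(1) Poland(3) Qatar(4)	Ao-aA1a1
El Deree db	Akhtal, 1968	2	Arabian Qatar(2)	Ao-aA1a1
Siglavy db	Siglavy Monterosa, 1907	8	Lipizzaner(7); Kladruber(1)	Ao-aA1a2
Siglavy db	Siglavy Capriola III, 1940	4	Lipizzaner(4)	Ao-aA1a2a	subline-HT
Siglavy db	21 Siglavy II, 1909	3	Shagya Arabian(1); Trakehner(2)	Ao-aA1b	private HT
Ibrahim db	Negatiw, 1945	8	Arabian Austria(1) Iran(2) Poland(2) Russia(2); Partbred Arabian(1)	Ao-aA1a3
Ibrahim db	Ferseyn, 1937	2	Arabian UAE(1); Pintabian(1)	Ao-aA1a3
Siglavy Bagdady db	Siglavy Bagdady VI, 1949	3	Arabian Germany(1); Shagya Arabian(1); Partbred Arabian(1)	Ao-aA1a5
Dahoman db	Dahoman XVI, 1904	1	Shagya Arabian(1)	Ao-aA3
Jamil El Kebir db	Anter, 1946	1	Arabian Germany(1)	Ao-aD2
Krzyzyk db	Enwer Bey, 1923	2	Arabian Poland(2)	Ao-aD2
Mirage db	Bey Shah, 1976	3	Arabian Qatar(1) Poland(2)	Ao-aD2
Kuhailan Haifi db	Bask, 1956	4	Arabian Poland(2) Qatar(1); Partbred Arabian(1)	Ao-aD2
Kuhailan Haifi db	Celebes, 1949	2	Arabian Austria(1) Iran(1)	Ao-aD2
Kuhailan Haifi db	Wielki Szlem, 1938	3	Arabian Poland(1) UAE(1); Warmblood(1)	Ao-aD2
Hadban db	Habdan XI, 1954	1	Shagya Arabian(1)	Ao-aD2
Gazlan db	Gazal VII, 1944	6	Shagya Arabian(6)	Ta*
O'Bajan db	O'Bajan VII-4 530, 1936	2	Shagya Arabian(2)	Ta*
O'Bajan db	O'Bajan X, 1929	2	Shagya Arabian(2)	Ta*
Shagya db	Shagya IV, 1875	3	Shagya Arabian(3)	Ta-s
Shagya db	Shagya VII, 1877	2	Shagya Arabian(2)	Ta-s
Shagya db	Shagya XI, 1886	3	Shagya Arabian(3)	Ta-s
Mersuch db	Mersuch IV, 1936	1	Shagya Arabian(1)	Ta-b
Bairactar db	Arax, 1952	3	Arabian Poland(1) Qatar(1) Russia(1)	Ta-b
Bairactar db	Gwarny, 1952	3	Arabian Germany(2) Poland(1)	Ta-bA	subline-HT
Dahman Amir db	Saludo, 1954	2	Arabian Qatar(1); Partbred Arabian(1)	Ta-b
Seanderich db	Tabal, 1952	1	Arabian Germany(1)	T2*
Kuhailan Afas db	Comet, 1953	2	Arabian Germany(1) Poland(1)	Tb-oB1*
Latif db	Baroud II, 1927	4	Arabian Qatar(3) Russia(1)	Tb-oB1*
Latif db	Kann, 1927	1	Arabian Russia(1)	Tb-oB1*
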